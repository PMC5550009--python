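"""Per-site editing levels, the pooled editing index, and site annotation.

The editing level of a site is G/(A+G) over reads covering it (counts
oriented to the site strand: a minus-strand site counts plus-strand T reads
as A and C reads as G).  Bases within a trim distance of either read end or
below a base-quality floor are ignored, and bases that are neither A nor G
are tallied separately and excluded from the level.  The editing index of a
site set pools the counts first: sum(G) / sum(A+G) -- the fraction of
inosines among all expressed adenosines -- which equals the
coverage-weighted mean of the per-site levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from thermedit.io_alignment import Genome, ReadAlignment

_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

PILEUP_COLUMNS = [
    "contig", "pos", "strand", "sample", "a_count", "g_count", "other_count",
    "coverage", "level",
]


def union_site_lists(*lists: pd.DataFrame, names: list[str] | None = None) -> pd.DataFrame:
    """Exact-coordinate union of site lists with per-source provenance flags.

    Each input needs columns contig/pos/strand.  Sites sharing (contig,
    pos) but disagreeing on strand are kept once (first-seen strand) with
    ``strand_conflict`` set and provenance from every source.
    """
    if names is None:
        names = [f"S{i + 1}" for i in range(len(lists))]
    if len(names) != len(lists):
        raise ValueError("names must match the number of lists")
    merged: dict[tuple[str, int], dict] = {}
    for name, df in zip(names, lists):
        for row in df.itertuples(index=False):
            key = (row.contig, row.pos)
            rec = merged.get(key)
            if rec is None:
                merged[key] = {
                    "contig": row.contig, "pos": row.pos, "strand": row.strand,
                    "sources": {name}, "strand_conflict": False,
                }
            else:
                rec["sources"].add(name)
                if rec["strand"] != row.strand:
                    rec["strand_conflict"] = True
    rows = []
    for key in sorted(merged):
        rec = merged[key]
        row = {
            "contig": rec["contig"], "pos": rec["pos"], "strand": rec["strand"],
            "strand_conflict": rec["strand_conflict"],
        }
        for name in names:
            row[f"in_{name}"] = name in rec["sources"]
        rows.append(row)
    cols = ["contig", "pos", "strand", "strand_conflict"] + [f"in_{n}" for n in names]
    return pd.DataFrame(rows, columns=cols)


def pileup_sites(
    alignments_by_sample: dict[str, list[ReadAlignment]] | list[ReadAlignment],
    sites: pd.DataFrame,
    genome: Genome | None = None,
    quality_min: int = 30,
    trim: int = 6,
) -> pd.DataFrame:
    """Per-site, per-sample A/G read counts at the listed sites.

    Bases within ``trim`` of either read end (in sequencing orientation) or
    with quality below ``quality_min`` are ignored.  Sites on contigs absent
    from every alignment simply get zero coverage; sites outside the genome
    (when a genome is given) are skipped and counted in the ``n_skipped``
    DataFrame attribute.
    """
    if not isinstance(alignments_by_sample, dict):
        alignments_by_sample = {"sample1": alignments_by_sample}
    site_rows = sites.reset_index(drop=True)
    skipped = 0
    if genome is not None:
        ok = [
            (row.contig in genome and 0 <= row.pos < genome.length(row.contig))
            for row in site_rows.itertuples(index=False)
        ]
        skipped = int(len(ok) - np.sum(ok))
        site_rows = site_rows[ok].reset_index(drop=True)
    by_contig: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for contig, grp in site_rows.groupby("contig", sort=False):
        order = np.argsort(grp["pos"].to_numpy(), kind="stable")
        by_contig[contig] = (
            grp["pos"].to_numpy()[order], grp.index.to_numpy()[order]
        )
    out = []
    for sample, alignments in alignments_by_sample.items():
        a = np.zeros(len(site_rows), dtype=int)
        g = np.zeros(len(site_rows), dtype=int)
        other = np.zeros(len(site_rows), dtype=int)
        strands = site_rows["strand"].to_numpy()
        for aln in alignments:
            if aln.contig not in by_contig:
                continue
            pos_arr, idx_arr = by_contig[aln.contig]
            lo = np.searchsorted(pos_arr, aln.start)
            hi = np.searchsorted(pos_arr, aln.end)
            if lo == hi:
                continue
            L = len(aln.seq)
            for k in range(lo, hi):
                off = int(pos_arr[k]) - aln.start
                read_pos = aln.read_position(off)
                if read_pos < trim or read_pos >= L - trim:
                    continue
                if ord(aln.qual[off]) - 33 < quality_min:
                    continue
                base = aln.seq[off]
                i = idx_arr[k]
                if strands[i] == "-":
                    base = _COMP1[base]
                if base == "A":
                    a[i] += 1
                elif base == "G":
                    g[i] += 1
                else:
                    other[i] += 1
        cov = a + g
        with np.errstate(invalid="ignore", divide="ignore"):
            level = np.where(cov > 0, g / np.maximum(cov, 1), np.nan)
        df = site_rows[["contig", "pos", "strand"]].copy()
        df["sample"] = sample
        df["a_count"] = a
        df["g_count"] = g
        df["other_count"] = other
        df["coverage"] = cov
        df["level"] = level
        out.append(df)
    result = pd.concat(out, ignore_index=True) if out else pd.DataFrame(columns=PILEUP_COLUMNS)
    result.attrs["n_skipped"] = skipped
    return result


def filter_supported(
    pileups: pd.DataFrame, min_reads: int = 2, min_level: float = 0.01
) -> pd.DataFrame:
    """Keep sites with >= min_reads G-supporting reads at a level >=
    min_level in at least one sample."""
    ok = (pileups["g_count"] >= min_reads) & (pileups["level"] >= min_level)
    keys = pileups.loc[ok, ["contig", "pos"]].drop_duplicates()
    kept = pileups.merge(keys, on=["contig", "pos"], how="inner")
    return kept.reset_index(drop=True)


@dataclass
class EditingIndex:
    """Pooled editing index: sum of G reads over sum of A+G reads."""

    numerator: int
    denominator: int

    @property
    def value(self) -> float:
        if self.denominator == 0:
            return float("nan")
        return self.numerator / self.denominator

    @property
    def defined(self) -> bool:
        return self.denominator > 0


def editing_index(pileups: pd.DataFrame, sample: str | None = None) -> EditingIndex:
    """Editing index over the pileup rows given (optionally one sample)."""
    df = pileups if sample is None else pileups[pileups["sample"] == sample]
    if len(df) == 0:
        return EditingIndex(numerator=0, denominator=0)
    return EditingIndex(
        numerator=int(df["g_count"].sum()),
        denominator=int((df["a_count"] + df["g_count"]).sum()),
    )


_CATEGORY_PRECEDENCE = [
    ("CDS", "CDS"),
    ("five_prime_utr", "5'UTR"),
    ("three_prime_utr", "3'UTR"),
    ("exon", "noncoding-exon"),
    ("gene", "intron"),
]


def _feature_trees(gene_model) -> dict[str, dict[str, IntervalTree]]:
    if isinstance(gene_model, dict):
        return gene_model
    trees: dict[str, dict[str, IntervalTree]] = {}
    for row in gene_model.itertuples(index=False):
        trees.setdefault(row.feature, {}).setdefault(
            row.contig, IntervalTree()
        ).addi(row.start, row.end, (row.gene_id, row.strand))
    return trees


def annotate_sites(sites: pd.DataFrame, gene_model) -> pd.DataFrame:
    """Assign one genomic category per site.

    Precedence: CDS > 5'UTR > 3'UTR > noncoding-exon > intron > intergenic;
    the lexicographically first gene id wins ties.  ``gene_model`` is either
    a feature DataFrame (contig, feature, start, end, strand, gene_id;
    0-based half-open) or the dict produced by ``load_intervals(.., "gtf")``.
    """
    trees = _feature_trees(gene_model)
    categories, genes = [], []
    for row in sites.itertuples(index=False):
        category, gene = "intergenic", None
        for feature, label in _CATEGORY_PRECEDENCE:
            contig_trees = trees.get(feature, {})
            tree = contig_trees.get(row.contig)
            if tree is None:
                continue
            hits = tree[row.pos]
            if hits:
                category = label
                gene = sorted(h.data[0] for h in hits)[0]
                break
        categories.append(category)
        genes.append(gene)
    out = sites.copy()
    out["category"] = categories
    out["gene_id"] = genes
    return out


def category_distribution(annotated: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions per genomic category."""
    counts = annotated["category"].value_counts()
    df = counts.rename_axis("category").reset_index(name="n_sites")
    df["fraction"] = df["n_sites"] / df["n_sites"].sum()
    return df


def gene_editing_counts(
    pileups: pd.DataFrame, site_genes: pd.DataFrame
) -> pd.DataFrame:
    """Pool pileup counts per gene.

    ``site_genes`` maps sites to genes (columns contig, pos, gene_id;
    e.g. the output of :func:`annotate_sites`).  Returns one row per gene
    with g_count and ag_count sums over that gene's sites and samples.
    """
    merged = pileups.merge(
        site_genes[["contig", "pos", "gene_id"]].dropna(subset=["gene_id"]),
        on=["contig", "pos"],
    )
    merged["ag_count"] = merged["a_count"] + merged["g_count"]
    out = (
        merged.groupby("gene_id", as_index=False)[["g_count", "ag_count"]]
        .sum()
        .sort_values("gene_id")
        .reset_index(drop=True)
    )
    return out
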