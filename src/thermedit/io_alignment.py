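"""Reference/read IO and the first-pass alignment contract.

Coordinates are 0-based half-open everywhere inside the package; 1-based
positions appear only in TSV site tables and reports (single conversion
point, see :func:`write_sites` / :func:`read_sites`).

The embedded aligner is a deliberately small exact-seed / ungapped-extend
mapper.  Downstream stages consume only its behavioral contract: reads with
a single best placement within the mismatch budget form the unique set,
reads with tied best placements are ambiguous, and reads that exceed the
budget everywhere land in the unaligned pool that feeds hyper-editing
detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

_COMP = str.maketrans("ACGTN", "TGCAN")

#: ordered (ref, read) mismatch pairs
MISMATCH_TYPES = [
    (a, b) for a in "ACGT" for b in "ACGT" if a != b
]


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMP)[::-1]


class Genome:
    """Uppercase ACGTN contigs with strand-aware subsequence lookup."""

    def __init__(self, contigs: dict[str, str]):
        if not contigs:
            raise ValueError("empty genome")
        self.contigs = {name: seq.upper() for name, seq in contigs.items()}
        for name, seq in self.contigs.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"contig {name!r} contains non-ACGTN characters: {sorted(bad)}")

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def length(self, name: str) -> int:
        return len(self.contigs[name])

    def names(self) -> list[str]:
        return list(self.contigs)

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Subsequence [start, end) of *contig*; reverse-complemented on '-'."""
        if contig not in self.contigs:
            raise KeyError(f"unknown contig {contig!r}")
        seq = self.contigs[contig]
        if start < 0 or end > len(seq) or start > end:
            raise IndexError(
                f"query {contig}:{start}-{end} outside contig bounds [0, {len(seq)})"
            )
        sub = seq[start:end]
        return revcomp(sub) if strand == "-" else sub


def load_reference(path: str | Path) -> Genome:
    """Load a FASTA reference. Duplicate contig names are an error."""
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig name {rec.id!r} in {path}")
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        raise ValueError(f"no sequences found in {path}")
    return Genome(contigs)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# reads

def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write (id, seq, qual) triples as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append((rec.id, str(rec.seq).upper(), qual))
    return reads


# ---------------------------------------------------------------------------
# alignment

@dataclass
class AlignParams:
    """First-pass alignment parameters.

    ``mismatch_per_100`` is the mismatch budget per 100 bp of read; reads
    that exceed it at every candidate locus go to the unaligned pool.
    """

    seed_len: int = 20
    n_seed_offsets: int = 3
    mismatch_per_100: float = 4.0

    def budget(self, read_len: int) -> int:
        return int(math.ceil(self.mismatch_per_100 * read_len / 100.0))


@dataclass
class ReadAlignment:
    """An ungapped unique placement of a read on the plus strand.

    ``seq``/``qual`` are stored plus-oriented (reverse-complemented /
    reversed for minus-strand placements); ``read_position`` converts a
    plus-strand offset back to the position in the read as sequenced.
    """

    read_id: str
    contig: str
    start: int
    strand: str
    seq: str
    qual: str
    n_mismatches: int

    @property
    def end(self) -> int:
        return self.start + len(self.seq)

    def read_position(self, offset: int) -> int:
        if self.strand == "+":
            return offset
        return len(self.seq) - 1 - offset


class GenomeIndex:
    """Exact k-mer index of the plus strand of every contig."""

    def __init__(self, genome: Genome, k: int = 20):
        self.genome = genome
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in genome.contigs.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self.index.setdefault(kmer, []).append((name, i))

    def seed_hits(self, seq: str, offsets: Sequence[int]) -> set[tuple[str, int]]:
        """Candidate (contig, read-start) placements from exact seeds."""
        hits: set[tuple[str, int]] = set()
        k = self.k
        for off in offsets:
            for contig, pos in self.index.get(seq[off : off + k], ()):
                start = pos - off
                if start >= 0:
                    hits.add((contig, start))
        return hits


def seed_offsets(read_len: int, k: int, n: int) -> list[int]:
    """Evenly spaced seed start offsets covering the read."""
    if read_len < k:
        return []
    if n <= 1:
        return [0]
    span = read_len - k
    offs = sorted({round(i * span / (n - 1)) for i in range(n)})
    return offs


def count_mismatches(a: str, b: str, limit: int) -> int:
    """Mismatches between equal-length strings, abandoning above *limit*."""
    if a == b:
        return 0
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


@dataclass
class AlignmentResult:
    unique: list[ReadAlignment]
    ambiguous: list[tuple[str, str, str]]
    unaligned: list[tuple[str, str, str]]

    def __iter__(self):
        return iter((self.unique, self.unaligned))


def align_reads(
    reads: Iterable[tuple[str, str, str]],
    genome: Genome,
    params: AlignParams | None = None,
    index: GenomeIndex | None = None,
) -> AlignmentResult:
    """Place reads on the genome; partition into unique / ambiguous / unaligned.

    A read is unique when a single placement attains the best (lowest)
    mismatch count within the budget; ties make it ambiguous; no placement
    within budget sends it to the unaligned pool (the hyper-editing input).
    """
    params = params or AlignParams()
    if index is None:
        index = GenomeIndex(genome, params.seed_len)
    unique: list[ReadAlignment] = []
    ambiguous: list[tuple[str, str, str]] = []
    unaligned: list[tuple[str, str, str]] = []
    for rid, seq, qual in reads:
        L = len(seq)
        budget = params.budget(L)
        offs = seed_offsets(L, params.seed_len, params.n_seed_offsets)
        best = budget + 1
        best_hits: list[tuple[str, int, str]] = []
        for strand in "+-":
            oriented = seq if strand == "+" else revcomp(seq)
            for contig, start in index.seed_hits(oriented, offs):
                ref = genome.contigs[contig]
                if start + L > len(ref):
                    continue
                mm = count_mismatches(oriented, ref[start : start + L], best)
                if mm < best:
                    best = mm
                    best_hits = [(contig, start, strand)]
                elif mm == best and best <= budget:
                    hit = (contig, start, strand)
                    if hit not in best_hits:
                        best_hits.append(hit)
        if best > budget or not best_hits:
            unaligned.append((rid, seq, qual))
        elif len(best_hits) > 1:
            ambiguous.append((rid, seq, qual))
        else:
            contig, start, strand = best_hits[0]
            oriented = seq if strand == "+" else revcomp(seq)
            oqual = qual if strand == "+" else qual[::-1]
            unique.append(
                ReadAlignment(rid, contig, start, strand, oriented, oqual, best)
            )
    return AlignmentResult(unique, ambiguous, unaligned)


# ---------------------------------------------------------------------------
# interval / site tables

def _bed_error(path, lineno, msg):
    return ValueError(f"{path}:{lineno}: malformed BED line ({msg})")


def load_intervals(path: str | Path, fmt: str = "bed"):
    """Load genomic intervals.

    BED (0-based half-open) returns ``{contig: IntervalTree}`` with the
    optional name column as interval data.  GTF (1-based inclusive on disk,
    converted to 0-based half-open) returns ``{feature_type: {contig:
    IntervalTree}}`` with ``(gene_id, strand)`` as data.
    """
    fmt = fmt.lower()
    if fmt == "bed":
        trees: dict[str, IntervalTree] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) < 3:
                    raise _bed_error(path, lineno, "fewer than 3 columns")
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError:
                    raise _bed_error(path, lineno, "non-integer coordinates") from None
                if end <= start:
                    raise _bed_error(path, lineno, f"end {end} <= start {start}")
                name = parts[3] if len(parts) > 3 else None
                trees.setdefault(parts[0], IntervalTree()).addi(start, end, name)
        return trees
    if fmt == "gtf":
        by_feature: dict[str, dict[str, IntervalTree]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 9:
                    raise ValueError(f"{path}:{lineno}: malformed GTF line")
                contig, _src, feature, start, end, _score, strand = parts[:7]
                attrs = parts[8]
                gene_id = None
                for token in attrs.split(";"):
                    token = token.strip()
                    if token.startswith("gene_id"):
                        gene_id = token.split(None, 1)[1].strip('" ')
                        break
                by_feature.setdefault(feature, {}).setdefault(
                    contig, IntervalTree()
                ).addi(int(start) - 1, int(end), (gene_id, strand))
        return by_feature
    raise ValueError(f"unknown interval format {fmt!r}")


def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    """Write (contig, start, end[, name]) tuples as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


SITE_COLUMNS = ["contig", "pos", "strand"]


def write_sites(sites: pd.DataFrame, path: str | Path) -> None:
    """Write a site table as TSV with a 1-based ``position`` column.

    In-memory tables carry a 0-based ``pos`` column; this is the only place
    the convention changes.
    """
    out = sites.copy()
    out.insert(list(out.columns).index("pos"), "position", out["pos"] + 1)
    out = out.drop(columns=["pos"])
    out.to_csv(path, sep="\t", index=False)


def read_sites(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "position" not in df.columns:
        raise ValueError(f"{path}: site table lacks a 1-based 'position' column")
    df.insert(list(df.columns).index("position"), "pos", df["position"] - 1)
    return df.drop(columns=["position"])


def write_gtf(features: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table (contig, feature, start, end 0-based half-open,
    strand, gene_id) as GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for row in features.itertuples(index=False):
            attrs = f'gene_id "{row.gene_id}"; transcript_id "{row.gene_id}.t1";'
            fh.write(
                "\t".join(
                    [
                        str(row.contig),
                        "thermedit",
                        str(row.feature),
                        str(row.start + 1),
                        str(row.end),
                        ".",
                        str(row.strand),
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
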