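"""Synthetic genomes, planted editing truth, and strand-balanced reads.

The generator encodes exactly the statistical structure the downstream
analysis assumes: clustered A-to-G editing at planted adenosines with
condition-dependent per-site rates, an ADAR-like sequence context (G
depleted immediately upstream of the edited A and enriched immediately
downstream), inverted repeats within 2 kb of a subset of clusters, a
uniform sequencing-error process, and reads drawn equally from both
strands.  One integer seed drives everything through deterministic
per-stage substreams, so identical configurations yield byte-identical
outputs.

Two condition regimes mirror the biology being modelled: a "cold-like"
regime (higher per-site editing rate) and a "warm-like" regime (lower
rate); the per-condition rates are configurable through
``SimConfig.per_site_edit_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from thermedit.io_alignment import Genome, revcomp

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A"}

# fixed substream labels so stage order never silently changes
_STAGE_IDS = {
    "genome": 0,
    "genes": 1,
    "plant": 2,
    "reads": 3,
    "track": 4,
    "folds": 5,
}


def stage_rng(seed: int, stage: str, sub: int = 0) -> np.random.Generator:
    """Deterministic per-stage random substream derived from the global seed."""
    return np.random.default_rng(np.random.SeedSequence((seed, _STAGE_IDS[stage], sub)))


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic dataset.

    per_site_edit_rate maps condition label -> per-site probability that a
    read covering a planted site carries the A->G conversion; the label
    order defines the condition order everywhere downstream.
    """

    genome_length: int = 200_000
    n_genes: int = 20
    n_clusters: int = 40
    sites_per_cluster: tuple[int, int] = (4, 8)
    per_site_edit_rate: dict[str, float] = field(
        default_factory=lambda: {"T18": 0.6, "T29": 0.2}
    )
    motif_g_upstream: float = 0.05
    motif_g_downstream: float = 0.40
    ir_fraction: float = 0.30
    ir_length: int = 40
    ir_max_distance: int = 2000
    seq_error_rate: float = 0.001
    read_length: int = 100
    coverage: float = 30.0
    quality_score: int = 40
    gene_fraction: float = 0.6
    contig_name: str = "chrS"
    seed: int = 0

    def __post_init__(self):
        probs = {
            "motif_g_upstream": self.motif_g_upstream,
            "motif_g_downstream": self.motif_g_downstream,
            "ir_fraction": self.ir_fraction,
            "seq_error_rate": self.seq_error_rate,
            "gene_fraction": self.gene_fraction,
            **{f"rate[{k}]": v for k, v in self.per_site_edit_rate.items()},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} = {p} outside [0, 1]")
        if self.genome_length <= 0 or self.read_length <= 0:
            raise ValueError("genome_length and read_length must be positive")
        if self.read_length > self.genome_length:
            raise ValueError("read_length exceeds genome_length")
        lo, hi = self.sites_per_cluster
        if lo < 1 or hi < lo:
            raise ValueError(f"bad sites_per_cluster range ({lo}, {hi})")

    @property
    def condition_labels(self) -> list[str]:
        return list(self.per_site_edit_rate)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sites_per_cluster"] = list(self.sites_per_cluster)
        return d


@dataclass
class PlantedTruth:
    """Ground truth emitted by the planting stage.

    sites: per-site (contig, pos 0-based, strand, condition->rate);
    clusters: (contig, start, end half-open over the site span, n_sites,
    strand); inverted_repeats: (contig, core_start, core_end, partner_start,
    partner_end).
    """

    sites: pd.DataFrame
    clusters: pd.DataFrame
    inverted_repeats: pd.DataFrame

    def rates(self, condition: str) -> np.ndarray:
        col = f"rate_{condition}"
        if col not in self.sites.columns:
            raise KeyError(f"unknown condition {condition!r}")
        return self.sites[col].to_numpy()


def generate_genome(config: SimConfig) -> tuple[Genome, pd.DataFrame]:
    """Uniform-composition random genome plus a simple gene model.

    The gene model tiles ``n_genes`` genes (alternating strand) over
    ``gene_fraction`` of the genome, each with a 5'UTR, three CDS exons
    separated by two introns, and a 3'UTR.
    """
    if config.genome_length < 10_000:
        raise ValueError("genome_length must be >= 10000")
    rng = stage_rng(config.seed, "genome")
    codes = rng.integers(0, 4, size=config.genome_length)
    seq = _BASE_BYTES[codes].tobytes().decode()
    genome = Genome({config.contig_name: seq})
    genes = _build_gene_model(config)
    return genome, genes


def _build_gene_model(config: SimConfig) -> pd.DataFrame:
    L, n = config.genome_length, config.n_genes
    rows = []
    if n <= 0:
        return pd.DataFrame(
            columns=["contig", "feature", "start", "end", "strand", "gene_id"]
        )
    gene_len = int(L * config.gene_fraction / n)
    spacer = (L - gene_len * n) // (n + 1)
    # within-gene layout as fractions of the gene length
    u5, ce, intr = 0.10, 0.15, 0.175
    for i in range(n):
        gstart = spacer + i * (gene_len + spacer)
        strand = "+" if i % 2 == 0 else "-"
        gid = f"g{i + 1:03d}"
        b = gstart
        utr5 = (b, b + int(u5 * gene_len))
        cds1 = (utr5[1], utr5[1] + int(ce * gene_len))
        in1 = (cds1[1], cds1[1] + int(intr * gene_len))
        cds2 = (in1[1], in1[1] + int(ce * gene_len))
        in2 = (cds2[1], cds2[1] + int(intr * gene_len))
        cds3 = (in2[1], in2[1] + int(ce * gene_len))
        utr3 = (cds3[1], gstart + gene_len)
        if strand == "-":  # mirror so the 5'UTR sits at the right end
            span = gstart + gene_len
            flip = lambda iv: (span - (iv[1] - gstart), span - (iv[0] - gstart))
            utr5, cds1, in1, cds2, in2, cds3, utr3 = (
                flip(utr5), flip(cds1), flip(in1), flip(cds2), flip(in2),
                flip(cds3), flip(utr3),
            )
        def add(feature, iv):
            rows.append(
                dict(contig=config.contig_name, feature=feature,
                     start=iv[0], end=iv[1], strand=strand, gene_id=gid)
            )
        add("gene", (gstart, gstart + gene_len))
        for iv in (cds1, cds2, cds3):
            add("CDS", iv)
            add("exon", iv)
        add("five_prime_utr", utr5)
        add("exon", utr5)
        add("three_prime_utr", utr3)
        add("exon", utr3)
    return pd.DataFrame(rows)


def _draw_flank_base(rng: np.random.Generator, p_g: float) -> str:
    if rng.random() < p_g:
        return "G"
    return "ACT"[rng.integers(0, 3)]


def plant_editing_clusters(genome: Genome, config: SimConfig) -> PlantedTruth:
    """Write clustered editable adenosines (and their ADAR-like context and
    optional inverted-repeat partners) into the genome; return the truth.

    The contig sequence is modified in place: site positions are set to A on
    the cluster strand, the immediately flanking bases are drawn from the
    motif-bias distributions, and for ``ir_fraction`` of clusters the
    reverse complement of the 40-nt cluster core is copied onto the same
    strand within ``ir_max_distance``.  Clusters are laid out in
    equal-width, non-overlapping slots so that truth intervals never
    collide.
    """
    rng = stage_rng(config.seed, "plant")
    contig = config.contig_name
    seq = list(genome.contigs[contig])
    L = len(seq)
    n = config.n_clusters
    slot = L // n if n else L
    need_span = max(int(np.ceil(0.10 * config.read_length)), 2)
    margin = config.ir_max_distance + config.ir_length + 100
    if slot < margin + need_span + 3 * config.sites_per_cluster[1] + 50:
        raise ValueError(
            f"cannot place {n} clusters with inverted-repeat partners within "
            f"{config.ir_max_distance} bp in a {L} bp genome: slot width {slot} "
            f"too small"
        )
    lo, hi = config.sites_per_cluster
    site_rows, cluster_rows, ir_rows = [], [], []
    for c in range(n):
        n_sites = int(rng.integers(lo, hi + 1))
        # alternate cluster strands so site calls are strand-balanced by
        # construction (the analysis expects an ~50/50 split)
        strand = "+" if c % 2 == 0 else "-"
        # inter-site gaps: at least 3 (flank writes must not collide), and the
        # span must reach 10% of the read while staying well inside one read
        gap_min = 3
        gap_max = max(gap_min, (config.read_length // 2 - 1) // max(n_sites - 1, 1))
        if n_sites > 1 and gap_max * (n_sites - 1) + 1 < need_span:
            raise ValueError(
                f"cannot reach cluster span {need_span} with {n_sites} sites "
                f"and read_length {config.read_length}"
            )
        for _ in range(100):
            if n_sites == 1:
                gaps = np.array([], dtype=int)
            else:
                gaps = rng.integers(gap_min, gap_max + 1, size=n_sites - 1)
            span = int(gaps.sum()) + 1
            if span >= need_span or n_sites == 1:
                break
        else:
            raise ValueError("could not draw a cluster span satisfying the 10% rule")
        start_lo = c * slot + 50
        start_hi = (c + 1) * slot - margin - span
        anchor = int(rng.integers(start_lo, start_hi))
        positions = anchor + np.concatenate([[0], np.cumsum(gaps)]).astype(int)
        for p in positions:
            seq[p] = "A" if strand == "+" else "T"
            up = _draw_flank_base(rng, config.motif_g_upstream)
            down = _draw_flank_base(rng, config.motif_g_downstream)
            if strand == "+":
                seq[p - 1] = up
                seq[p + 1] = down
            else:
                seq[p + 1] = _COMP1[up]
                seq[p - 1] = _COMP1[down]
            row = dict(contig=contig, pos=int(p), strand=strand, cluster=c)
            for label, rate in config.per_site_edit_rate.items():
                row[f"rate_{label}"] = rate
            site_rows.append(row)
        cstart, cend = int(positions[0]), int(positions[-1]) + 1
        cluster_rows.append(
            dict(contig=contig, start=cstart, end=cend, n_sites=n_sites, strand=strand)
        )
        if rng.random() < config.ir_fraction:
            mid = (cstart + cend) // 2
            core_start = max(cstart - (config.ir_length - (cend - cstart)) // 2, 0)
            core_start = min(core_start, mid - config.ir_length // 2)
            core_start = max(core_start, c * slot)
            core_end = core_start + config.ir_length
            offset = int(rng.integers(200, config.ir_max_distance - config.ir_length))
            pstart = cend + offset
            pend = pstart + config.ir_length
            core = "".join(seq[core_start:core_end])
            partner = revcomp(core)
            seq[pstart:pend] = list(partner)
            ir_rows.append(
                dict(contig=contig, core_start=core_start, core_end=core_end,
                     partner_start=pstart, partner_end=pend, cluster=c)
            )
    genome.contigs[contig] = "".join(seq)
    sites = pd.DataFrame(site_rows).sort_values("pos").reset_index(drop=True)
    clusters = pd.DataFrame(cluster_rows)
    irs = pd.DataFrame(
        ir_rows,
        columns=["contig", "core_start", "core_end", "partner_start",
                 "partner_end", "cluster"],
    )
    return PlantedTruth(sites=sites, clusters=clusters, inverted_repeats=irs)


def simulate_reads(
    genome: Genome,
    truth: PlantedTruth,
    condition: str,
    config: SimConfig,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Strand-balanced single-end reads with planted edits and uniform errors.

    Returns ``(reads, read_edits)`` where reads are (id, seq, qual) triples
    and ``read_edits`` records every A->G conversion actually written into a
    read (read id, contig, pos).
    """
    if condition not in config.per_site_edit_rate:
        raise KeyError(f"unknown condition {condition!r}")
    if config.coverage <= 0:
        raise ValueError("coverage must be positive")
    cond_idx = config.condition_labels.index(condition)
    rng = stage_rng(config.seed, "reads", cond_idx)
    contig = config.contig_name
    ref = genome.contigs[contig]
    L = len(ref)
    rl = config.read_length
    n_reads = int(round(config.coverage * L / rl))
    starts = rng.integers(0, L - rl + 1, size=n_reads)
    minus = rng.random(n_reads) < 0.5
    n_errors = rng.binomial(rl, config.seq_error_rate, size=n_reads)
    site_pos = truth.sites["pos"].to_numpy()
    site_strand = truth.sites["strand"].to_numpy()
    rates = truth.rates(condition)
    qual = chr(33 + config.quality_score) * rl
    reads: list[tuple[str, str, str]] = []
    edit_rows: list[tuple[str, str, int]] = []
    for i in range(n_reads):
        start = int(starts[i])
        rid = f"r{condition}_{i}"
        lo = int(np.searchsorted(site_pos, start))
        hi = int(np.searchsorted(site_pos, start + rl))
        k_err = int(n_errors[i])
        if lo == hi and k_err == 0:
            s = ref[start : start + rl]
            reads.append((rid, revcomp(s) if minus[i] else s, qual))
            continue
        chars = list(ref[start : start + rl])
        for j in range(lo, hi):
            if rng.random() < rates[j]:
                off = int(site_pos[j]) - start
                # edited base in plus-strand representation
                chars[off] = "G" if site_strand[j] == "+" else "C"
                edit_rows.append((rid, contig, int(site_pos[j])))
        if minus[i]:
            chars = list(revcomp("".join(chars)))
        for _ in range(k_err):
            p = int(rng.integers(0, rl))
            alts = [b for b in "ACGT" if b != chars[p]]
            chars[p] = alts[int(rng.integers(0, 3))]
        reads.append((rid, "".join(chars), qual))
    read_edits = pd.DataFrame(edit_rows, columns=["read_id", "contig", "pos"])
    return reads, read_edits


def simulate_conservation_track(
    genome: Genome,
    truth: PlantedTruth,
    config: SimConfig,
    baseline: float = 0.2,
    elevated: float = 0.8,
    halfwidth: int = 10,
) -> dict[str, np.ndarray]:
    """Per-base conservation scores: noisy baseline with bumps at truth sites."""
    rng = stage_rng(config.seed, "track")
    track: dict[str, np.ndarray] = {}
    for name, seq in genome.contigs.items():
        arr = np.clip(rng.normal(baseline, 0.05, size=len(seq)), 0.0, 1.0)
        track[name] = arr
    for row in truth.sites.itertuples(index=False):
        arr = track[row.contig]
        lo = max(row.pos - halfwidth, 0)
        hi = min(row.pos + halfwidth + 1, len(arr))
        arr[lo:hi] = np.clip(
            elevated + rng.normal(0.0, 0.02, size=hi - lo), 0.0, 1.0
        )
    return track


def simulate_fold_intervals(
    truth: PlantedTruth, config: SimConfig, fraction: float = 0.25, pad: int = 10
) -> list[tuple[str, int, int]]:
    """BED-style intervals marking a random subset of truth clusters as
    conserved-structure regions."""
    rng = stage_rng(config.seed, "folds")
    out = []
    for row in truth.clusters.itertuples(index=False):
        if rng.random() < fraction:
            out.append((row.contig, max(row.start - pad, 0), row.end + pad))
    return out


def write_truth(truth: PlantedTruth, prefix: str) -> None:
    """Write truth tables: sites TSV (1-based), clusters/IR BED (0-based)."""
    from thermedit.io_alignment import write_sites, write_bed

    write_sites(truth.sites, f"{prefix}.sites.tsv")
    write_bed(
        [
            (r.contig, r.start, r.end, f"cluster{i}")
            for i, r in enumerate(truth.clusters.itertuples(index=False))
        ],
        f"{prefix}.clusters.bed",
    )
    write_bed(
        [
            (r.contig, r.partner_start, r.partner_end, f"ir{i}")
            for i, r in enumerate(truth.inverted_repeats.itertuples(index=False))
        ],
        f"{prefix}.inverted_repeats.bed",
    )
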