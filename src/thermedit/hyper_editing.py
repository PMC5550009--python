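"""Hyper-edited read detection by base-transformed realignment.

Reads that standard alignment rejects because they carry dense A-to-G
mismatch clusters are recovered by collapsing the mismatch type: both the
read and the genome are transformed (every ``from_base`` replaced by
``to_base``), the read is realigned in the reduced alphabet requiring a
unique placement, and the original sequences are then compared to recover
the mismatches.  High-quality mismatches of the target type form a
read-level cluster, kept only if it has enough edits, spans at least 10% of
the read, and keeps clear of the read ends.  Genomic merging of clusters
(gap <= 20 nt) yields hyper-edited regions.

A-to-I editing appears as A>G on the edited strand, so editing detection
runs the A>G transform (plus-strand sites) and the T>C transform
(minus-strand sites, observed through the plus-strand alignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from thermedit.io_alignment import (
    AlignParams,
    Genome,
    GenomeIndex,
    MISMATCH_TYPES,
    count_mismatches,
    revcomp,
    seed_offsets,
)

_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def transform(sequence: str, from_base: str, to_base: str) -> str:
    """Collapse one base into another (e.g. A>G), preserving length."""
    for b in (from_base, to_base):
        if b not in "ACGT":
            raise ValueError(f"invalid base {b!r}")
    if from_base == to_base:
        raise ValueError("from_base and to_base must differ")
    return sequence.replace(from_base, to_base)


@dataclass
class HyperParams:
    """Cluster-calling parameters.

    quality_min: Phred floor for a mismatch to count as high quality.
    min_edits: minimum target-type mismatches per read cluster.
    end_exclusion: mismatches within this many bases of either read end are
        discarded before the cluster rules are applied.
    span_fraction: first-to-last mismatch span must cover at least this
        fraction of the read length.
    max_gap: maximum genomic gap between clusters merged into one region.
    """

    quality_min: int = 30
    min_edits: int = 4
    end_exclusion: int = 6
    span_fraction: float = 0.10
    max_gap: int = 20
    align: AlignParams = field(default_factory=AlignParams)


@dataclass
class MismatchEvent:
    read_id: str
    contig: str
    pos: int          # genomic, 0-based, plus-strand coordinate
    read_pos: int     # position in the read as sequenced
    ref_base: str
    read_base: str
    qual: int


@dataclass
class HyperEditedCluster:
    read_id: str
    contig: str
    start: int        # genomic position of the first high-quality mismatch
    end: int          # one past the last mismatch (half-open)
    strand: str       # strand on which the reference base is the edited base
    read_length: int
    mismatch_type: tuple[str, str]
    events: list[MismatchEvent]

    @property
    def n_edits(self) -> int:
        return len(self.events)

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class HyperEditedRegion:
    contig: str
    start: int
    end: int
    strand: str
    cluster_ids: list[int]
    n_sites: int
    n_events: int


class TransformedRealigner:
    """Caches transformed genomes and their k-mer indexes per mismatch type."""

    def __init__(self, genome: Genome, params: AlignParams | None = None):
        self.genome = genome
        self.params = params or AlignParams()
        self._cache: dict[tuple[str, str], tuple[Genome, GenomeIndex]] = {}

    def get(self, from_base: str, to_base: str) -> tuple[Genome, GenomeIndex]:
        key = (from_base, to_base)
        if key not in self._cache:
            tcontigs = {
                name: transform(seq, from_base, to_base)
                for name, seq in self.genome.contigs.items()
            }
            tgenome = Genome(tcontigs)
            self._cache[key] = (tgenome, GenomeIndex(tgenome, self.params.seed_len))
        return self._cache[key]

    def realign(
        self, seq: str, from_base: str, to_base: str
    ) -> tuple[str, int, str] | None:
        """Unique placement of the transformed read, or None.

        Both orientations compete: each oriented copy of the read is
        transformed and matched against the transformed plus strand.
        Returns (contig, start, orientation) for a strictly unique best
        placement within the mismatch budget; ties or budget failure give
        None.
        """
        tgenome, index = self.get(from_base, to_base)
        L = len(seq)
        budget = self.params.budget(L)
        offs = seed_offsets(L, self.params.seed_len, self.params.n_seed_offsets)
        best = budget + 1
        best_hits: list[tuple[str, int, str]] = []
        for strand in "+-":
            oriented = seq if strand == "+" else revcomp(seq)
            toriented = transform(oriented, from_base, to_base)
            for contig, start in index.seed_hits(toriented, offs):
                ref = tgenome.contigs[contig]
                if start + L > len(ref):
                    continue
                mm = count_mismatches(toriented, ref[start : start + L], best)
                if mm < best:
                    best = mm
                    best_hits = [(contig, start, strand)]
                elif mm == best and best <= budget:
                    hit = (contig, start, strand)
                    if hit not in best_hits:
                        best_hits.append(hit)
        if best > budget or len(best_hits) != 1:
            return None
        return best_hits[0]


def _site_strand(mismatch_type: tuple[str, str]) -> str:
    # a run whose reference base is A or C reports plus-strand events; T/G
    # runs are the same biological event class seen from the minus strand
    return "+" if mismatch_type[0] in "AC" else "-"


def detect_hyper_edited_reads(
    pool,
    genome: Genome,
    mismatch_type: tuple[str, str] = ("A", "G"),
    params: HyperParams | None = None,
    realigner: TransformedRealigner | None = None,
) -> tuple[list[HyperEditedCluster], dict]:
    """Recover hyper-edited reads of one mismatch type from the unaligned pool.

    Returns the clusters that pass all three rules plus a QC dictionary
    with attrition counts (no placement / ambiguous placement / failed
    cluster rules).
    """
    params = params or HyperParams()
    if tuple(mismatch_type) not in {tuple(t) for t in MISMATCH_TYPES}:
        raise ValueError(f"invalid mismatch type {mismatch_type!r}")
    frm, to = mismatch_type
    if realigner is None:
        realigner = TransformedRealigner(genome, params.align)
    strand = _site_strand(mismatch_type)
    stats = {"n_pool": 0, "no_hit": 0, "ambiguous_or_no_hit": 0, "failed_rules": 0}
    clusters: list[HyperEditedCluster] = []
    for rid, seq, qual in pool:
        stats["n_pool"] += 1
        hit = realigner.realign(seq, frm, to)
        if hit is None:
            stats["ambiguous_or_no_hit"] += 1
            continue
        contig, start, orient = hit
        oriented = seq if orient == "+" else revcomp(seq)
        L = len(seq)
        ref = genome.contigs[contig][start : start + L]
        events: list[MismatchEvent] = []
        for i in range(L):
            if ref[i] == frm and oriented[i] == to:
                read_pos = i if orient == "+" else L - 1 - i
                q = ord(qual[read_pos]) - 33
                if q < params.quality_min:
                    continue
                if read_pos < params.end_exclusion or read_pos >= L - params.end_exclusion:
                    continue
                events.append(
                    MismatchEvent(rid, contig, start + i, read_pos, frm, to, q)
                )
        if len(events) < params.min_edits:
            stats["failed_rules"] += 1
            continue
        first = min(e.pos for e in events)
        last = max(e.pos for e in events)
        if (last - first + 1) < params.span_fraction * L:
            stats["failed_rules"] += 1
            continue
        clusters.append(
            HyperEditedCluster(
                read_id=rid, contig=contig, start=first, end=last + 1,
                strand=strand, read_length=L, mismatch_type=(frm, to),
                events=events,
            )
        )
    return clusters, stats


def detect_editing(
    pool, genome: Genome, params: HyperParams | None = None,
    realigner: TransformedRealigner | None = None,
) -> tuple[list[HyperEditedCluster], dict]:
    """A-to-G editing on both strands: A>G run (plus) plus T>C run (minus)."""
    params = params or HyperParams()
    if realigner is None:
        realigner = TransformedRealigner(genome, params.align)
    plus, s1 = detect_hyper_edited_reads(pool, genome, ("A", "G"), params, realigner)
    minus, s2 = detect_hyper_edited_reads(pool, genome, ("T", "C"), params, realigner)
    stats = {k: s1[k] + s2[k] for k in s1}
    return plus + minus, stats


def merge_clusters_to_regions(
    clusters: list[HyperEditedCluster], max_gap: int = 20
) -> list[HyperEditedRegion]:
    """Merge overlapping or near clusters (genomic gap <= max_gap) per
    contig and strand; region boundaries run from the first base of the
    upstream cluster to the last base of the downstream cluster."""
    order = sorted(
        range(len(clusters)),
        key=lambda i: (clusters[i].contig, clusters[i].strand, clusters[i].start,
                       clusters[i].end),
    )
    regions: list[HyperEditedRegion] = []
    current: list[int] = []

    def flush():
        if not current:
            return
        members = [clusters[i] for i in current]
        positions = {e.pos for c in members for e in c.events}
        regions.append(
            HyperEditedRegion(
                contig=members[0].contig,
                start=min(c.start for c in members),
                end=max(c.end for c in members),
                strand=members[0].strand,
                cluster_ids=list(current),
                n_sites=len(positions),
                n_events=sum(c.n_edits for c in members),
            )
        )

    prev = None
    cur_end = None
    for i in order:
        c = clusters[i]
        key = (c.contig, c.strand)
        if prev == key and c.start - cur_end <= max_gap:
            current.append(i)
            cur_end = max(cur_end, c.end)
        else:
            flush()
            current = [i]
            cur_end = c.end
            prev = key
    flush()
    return regions


def collect_sites(
    clusters: list[HyperEditedCluster],
) -> tuple[pd.DataFrame, dict]:
    """Unique editing-site calls and summary statistics.

    Each event is one read supporting an edited adenosine; a site is a
    unique (contig, position, strand).  The summary reports the unique site
    count, total events, events per site, mean sites per cluster and mean
    cluster length.
    """
    counts: dict[tuple[str, int, str], int] = {}
    for c in clusters:
        for e in c.events:
            key = (c.contig, e.pos, c.strand)
            counts[key] = counts.get(key, 0) + 1
    rows = [
        dict(contig=k[0], pos=k[1], strand=k[2], n_events=v)
        for k, v in sorted(counts.items())
    ]
    sites = pd.DataFrame(rows, columns=["contig", "pos", "strand", "n_events"])
    n_events = int(sites["n_events"].sum()) if len(sites) else 0
    summary = {
        "n_sites": len(sites),
        "n_events": n_events,
        "n_clusters": len(clusters),
        "events_per_site": n_events / len(sites) if len(sites) else float("nan"),
        "mean_sites_per_cluster": (
            float(np.mean([c.n_edits for c in clusters])) if clusters else float("nan")
        ),
        "mean_cluster_length": (
            float(np.mean([c.span for c in clusters])) if clusters else float("nan")
        ),
    }
    return sites, summary


def qc_mismatch_spectrum(
    pool, genome: Genome, params: HyperParams | None = None,
    realigner: TransformedRealigner | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run all 12 transformed realignments for QC.

    Returns a 12-row table (ref, alt, strand, run, n_sites, n_events): each
    run X>Y is reported on the strand where the reference base is X,
    canonicalized so that ref is A or C on the plus strand (a T>C run is
    A>G editing on the minus strand).  The second table is the read-position
    histogram of A>G events (both strands), which should be flat away from
    the excluded read ends for genuine editing.
    """
    params = params or HyperParams()
    if realigner is None:
        realigner = TransformedRealigner(genome, params.align)
    rows = []
    pos_counts: dict[int, int] = {}
    for frm, to in MISMATCH_TYPES:
        clusters, _ = detect_hyper_edited_reads(
            pool, genome, (frm, to), params, realigner
        )
        sites, summary = collect_sites(clusters)
        strand = _site_strand((frm, to))
        ref, alt = (frm, to) if strand == "+" else (_COMP1[frm], _COMP1[to])
        rows.append(
            dict(ref=ref, alt=alt, strand=strand, run=f"{frm}>{to}",
                 n_sites=summary["n_sites"], n_events=summary["n_events"])
        )
        if (ref, alt) == ("A", "G"):
            for c in clusters:
                for e in c.events:
                    pos_counts[e.read_pos] = pos_counts.get(e.read_pos, 0) + 1
    spectrum = pd.DataFrame(rows)
    hist = pd.DataFrame(
        sorted(pos_counts.items()), columns=["read_pos", "n_events"]
    )
    return spectrum, hist


def a2g_share(spectrum: pd.DataFrame) -> float:
    """Fraction of all called sites that are A>G (either strand)."""
    total = spectrum["n_sites"].sum()
    if total == 0:
        return float("nan")
    a2g = spectrum.loc[
        (spectrum["ref"] == "A") & (spectrum["alt"] == "G"), "n_sites"
    ].sum()
    return float(a2g / total)


def strand_split(sites: pd.DataFrame) -> float:
    """Fraction of sites called on the plus strand."""
    if len(sites) == 0:
        return float("nan")
    return float((sites["strand"] == "+").mean())


def compute_motif(
    sites: pd.DataFrame, genome: Genome, flank: int = 5
) -> tuple[pd.DataFrame, int]:
    """Position frequency matrix of the sequence context around edited sites.

    Offsets run -flank..+flank in the 5'->3' direction of the site strand;
    offset 0 is the edited adenosine.  Rows sum to 1.  Sites whose window
    leaves the contig are skipped; their count is returned alongside.
    """
    if len(sites) == 0:
        raise ValueError("no sites provided")
    counts = np.zeros((2 * flank + 1, 4), dtype=float)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    skipped = 0
    for row in sites.itertuples(index=False):
        start, end = row.pos - flank, row.pos + flank + 1
        if start < 0 or end > genome.length(row.contig):
            skipped += 1
            continue
        window = genome.fetch(row.contig, start, end, row.strand)
        for k, b in enumerate(window):
            if b in base_idx:
                counts[k, base_idx[b]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    freqs = counts / totals
    pfm = pd.DataFrame(
        freqs, index=range(-flank, flank + 1), columns=list("ACGT")
    )
    pfm.index.name = "offset"
    return pfm, skipped
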