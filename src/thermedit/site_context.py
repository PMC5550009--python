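"""Structure and conservation context of editing sites.

ADAR requires double-stranded RNA, so a genuine editing site should have a
nearby sequence able to base-pair with it.  For each site (or hyper-edited
region) a 40-nt window centered on the site is aligned against the
reverse complement of the same-strand flanking sequence within 2 kb
("antisense" mode); aligning against the flank as-is ("sense" mode) is the
negative control, and "edited" modes first substitute G for A at the known
edited positions to ask how editing itself changes the predicted duplex.
The local aligner is a word-seeded, affine-gap extender in the spirit of
blastn (exact 7-mer seeds; match +2, mismatch -3, gap open 2, extend 2 per
base); a window is "matched" when the best local alignment reaches 70%
identity over at least 70% of the window.

Conservation context: per-offset mean of a per-base conservation track
around sites, stratified by event support, against a background of
randomly chosen adenosines.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from thermedit.io_alignment import Genome, revcomp

_NEG = float("-inf")


@dataclass
class StructureParams:
    match: int = 2
    mismatch: int = -3
    gap_open: int = 2     # cost of a gap of length g is gap_open + gap_extend * g
    gap_extend: int = 2
    word: int = 7
    min_identity: float = 70.0
    min_coverage: float = 70.0
    flank: int = 2000
    window: int = 40


@dataclass
class LocalHit:
    """Best seeded local alignment of a query window against a subject."""

    score: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    n_match: int
    n_cols: int

    @property
    def identity(self) -> float:
        return 100.0 * self.n_match / self.n_cols if self.n_cols else 0.0


def _extend(A: str, B: str, p: StructureParams) -> tuple[float, int, int, int, int]:
    """Anchored affine-gap extension.

    Best alignment of a prefix of A with a prefix of B that starts exactly
    at the (0,0) corner (abutting a seed) with a free far end.  Returns
    (score, a_used, b_used, n_match, n_cols); the empty extension scores 0.
    """
    la, lb = len(A), len(B)
    if la == 0 or lb == 0:
        return 0.0, 0, 0, 0, 0
    go, ge = p.gap_open + p.gap_extend, p.gap_extend
    # state matrices and traceback pointers (0=M,1=X(gap in B),2=Y(gap in A))
    M = [[_NEG] * (lb + 1) for _ in range(la + 1)]
    X = [[_NEG] * (lb + 1) for _ in range(la + 1)]
    Y = [[_NEG] * (lb + 1) for _ in range(la + 1)]
    ptrM = [[0] * (lb + 1) for _ in range(la + 1)]
    ptrX = [[0] * (lb + 1) for _ in range(la + 1)]
    ptrY = [[0] * (lb + 1) for _ in range(la + 1)]
    M[0][0] = 0.0
    for i in range(1, la + 1):
        X[i][0] = -(p.gap_open + p.gap_extend * i)
        ptrX[i][0] = 0 if i == 1 else 1
    for j in range(1, lb + 1):
        Y[0][j] = -(p.gap_open + p.gap_extend * j)
        ptrY[0][j] = 0 if j == 1 else 2
    best, bi, bj = 0.0, 0, 0
    for i in range(1, la + 1):
        ai = A[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        pMi, pXi, pYi = ptrM[i], ptrX[i], ptrY[i]
        for j in range(1, lb + 1):
            sub = p.match if ai == B[j - 1] else p.mismatch
            m0, x0, y0 = Mp[j - 1], Xp[j - 1], Yp[j - 1]
            if m0 >= x0 and m0 >= y0:
                Mi[j], pMi[j] = m0 + sub, 0
            elif x0 >= y0:
                Mi[j], pMi[j] = x0 + sub, 1
            else:
                Mi[j], pMi[j] = y0 + sub, 2
            mo, xo = Mp[j] - go, Xp[j] - ge
            if mo >= xo:
                Xi[j], pXi[j] = mo, 0
            else:
                Xi[j], pXi[j] = xo, 1
            my, yy = Mi[j - 1] - go, Yi[j - 1] - ge
            if my >= yy:
                Yi[j], pYi[j] = my, 0
            else:
                Yi[j], pYi[j] = yy, 2
            if Mi[j] > best:
                best, bi, bj = Mi[j], i, j
    if best <= 0.0:
        return 0.0, 0, 0, 0, 0
    # traceback from the best match-state cell
    i, j, state = bi, bj, 0
    n_match = n_cols = 0
    while i > 0 or j > 0:
        n_cols += 1
        if state == 0:
            if A[i - 1] == B[j - 1]:
                n_match += 1
            state = ptrM[i][j]
            i, j = i - 1, j - 1
        elif state == 1:
            state = ptrX[i][j]
            i -= 1
        else:
            state = ptrY[i][j]
            j -= 1
    return best, bi, bj, n_match, n_cols


def seeded_local_align(
    query: str, subject: str, params: StructureParams | None = None
) -> LocalHit | None:
    """Best local alignment through an exact word seed.

    Every exact ``word``-length match between query and subject is extended
    on both sides with an anchored affine-gap DP (the extension search
    space is capped: no useful alignment shifts the subject by more than a
    window length, because total gap cost is bounded by total match gain).
    Returns None when no seed exists.
    """
    p = params or StructureParams()
    m = len(query)
    w = p.word
    if m < w or len(subject) < w:
        return None
    seeds: list[tuple[int, int]] = []
    for i in range(m - w + 1):
        word = query[i : i + w]
        j = subject.find(word)
        while j != -1:
            seeds.append((i, j))
            j = subject.find(word, j + 1)
    if not seeds:
        return None
    best_hit: LocalHit | None = None
    perfect = p.match * m
    for i, j in seeds:
        cap = m  # gap slack bound: gaps cannot outscore total match gain
        b0 = max(0, j - (i + cap))
        ls, la_used, lb_used, lm, lc = _extend(
            query[:i][::-1], subject[b0:j][::-1], p
        )
        rq = query[i + w :]
        rs = subject[j + w : j + w + len(rq) + cap]
        rs_score, ra_used, rb_used, rm, rc = _extend(rq, rs, p)
        score = p.match * w + ls + rs_score
        if best_hit is None or score > best_hit.score:
            best_hit = LocalHit(
                score=score,
                q_start=i - la_used,
                q_end=i + w + ra_used,
                s_start=j - lb_used,
                s_end=j + w + rb_used,
                n_match=w + lm + rm,
                n_cols=w + lc + rc,
            )
            if score >= perfect:
                break
    return best_hit


# ---------------------------------------------------------------------------
# window extraction and the inverted-complement search

def extract_window(
    genome: Genome, contig: str, pos: int, strand: str, width: int = 40
) -> tuple[str, int, int, bool]:
    """Site-strand-oriented window with the site at position width//2
    (0-based index 19 of a 40-nt window).

    Returns (sequence, plus_start, plus_end, truncated); windows running
    off the contig are truncated with the flag set.
    """
    center_left = width // 2 - 1 if strand == "+" else width // 2
    start = pos - center_left
    end = start + width
    L = genome.length(contig)
    truncated = start < 0 or end > L
    start_c, end_c = max(start, 0), min(end, L)
    seq = genome.fetch(contig, start_c, end_c, strand)
    return seq, start_c, end_c, truncated


@dataclass
class StructureMatch:
    contig: str
    center: int
    strand: str
    mode: str
    score: float
    identity: float
    coverage: float
    matched: bool
    partner_start: int | None
    partner_end: int | None
    truncated: bool

    def as_dict(self) -> dict:
        return dict(
            contig=self.contig, center=self.center, strand=self.strand,
            mode=self.mode, score=self.score, identity=self.identity,
            coverage=self.coverage, matched=self.matched,
            partner_start=self.partner_start, partner_end=self.partner_end,
            truncated=self.truncated,
        )


MODES = ("antisense", "sense", "antisense-edited", "sense-edited")


def _map_back(plus_start: int, plus_end: int, orient: str, s0: int, s1: int):
    if orient == "+":
        return plus_start + s0, plus_start + s1
    return plus_end - s1, plus_end - s0


def search_inverted_complement(
    genome: Genome,
    contig: str,
    pos: int,
    strand: str,
    params: StructureParams | None = None,
    edited_offsets: tuple[int, ...] = (),
) -> dict[str, StructureMatch]:
    """Search the +-2 kb same-strand flanks for a partner able to pair with
    the window around a site.

    Returns one StructureMatch per mode.  ``edited_offsets`` are
    window-oriented offsets of known edited adenosines; the edited modes
    substitute G there before searching.
    """
    p = params or StructureParams()
    window, wstart, wend, truncated = extract_window(
        genome, contig, pos, strand, p.window
    )
    L = genome.length(contig)
    up_plus = (max(0, wstart - p.flank), wstart)
    down_plus = (wend, min(L, wend + p.flank))
    # same-strand flank sequences, oriented on the site strand
    flanks = []
    for (a, b) in (up_plus, down_plus):
        if b - a >= p.word:
            flanks.append((genome.fetch(contig, a, b, strand), a, b, strand))
    edited = list(window)
    for off in edited_offsets:
        if 0 <= off < len(edited):
            edited[off] = "G"
    edited_window = "".join(edited)
    out: dict[str, StructureMatch] = {}
    for mode in MODES:
        q = edited_window if mode.endswith("edited") else window
        best: LocalHit | None = None
        best_partner = None
        for seq, a, b, orient in flanks:
            if mode.startswith("antisense"):
                subject = revcomp(seq)
                sub_orient = "-" if orient == "+" else "+"
            else:
                subject = seq
                sub_orient = orient
            hit = seeded_local_align(q, subject, p)
            if hit is not None and (best is None or hit.score > best.score):
                best = hit
                if sub_orient == orient:
                    best_partner = _map_back(a, b, "+" if orient == "+" else "-",
                                             hit.s_start, hit.s_end)
                else:
                    # subject was reverse-complemented relative to the plus slice
                    s0, s1 = hit.s_start, hit.s_end
                    if orient == "+":
                        best_partner = (b - s1, b - s0)
                    else:
                        best_partner = (a + s0, a + s1)
        if best is None:
            out[mode] = StructureMatch(
                contig, pos, strand, mode, 0.0, 0.0, 0.0, False, None, None,
                truncated,
            )
            continue
        coverage = 100.0 * (best.q_end - best.q_start) / max(len(window), 1)
        identity = best.identity
        matched = identity >= p.min_identity and coverage >= p.min_coverage
        out[mode] = StructureMatch(
            contig, pos, strand, mode, best.score, identity, coverage, matched,
            best_partner[0] if best_partner else None,
            best_partner[1] if best_partner else None,
            truncated,
        )
    return out


def search_sites(
    genome: Genome,
    sites: pd.DataFrame,
    params: StructureParams | None = None,
    center_offset: int | None = None,
) -> pd.DataFrame:
    """Run the inverted-complement search for every site; long DataFrame of
    matches (one row per site x mode).  The edited-form modes substitute G
    at the window center (the site itself)."""
    p = params or StructureParams()
    center = center_offset if center_offset is not None else p.window // 2 - 1
    rows = []
    for row in sites.itertuples(index=False):
        matches = search_inverted_complement(
            genome, row.contig, row.pos, row.strand, p, edited_offsets=(center,)
        )
        for m in matches.values():
            d = m.as_dict()
            if hasattr(row, "condition"):
                d["condition"] = row.condition
            rows.append(d)
    return pd.DataFrame(rows)


def structure_summary(matches: pd.DataFrame) -> pd.DataFrame:
    """Fraction of sites matched per mode (and per condition when present),
    with the antisense-minus-sense excess as the structure signal."""
    keys = ["condition", "mode"] if "condition" in matches.columns else ["mode"]
    grp = matches.groupby(keys, as_index=False).agg(
        n=("matched", "size"), n_matched=("matched", "sum")
    )
    grp["fraction"] = grp["n_matched"] / grp["n"]
    if "condition" in matches.columns:
        piv = grp.pivot(index="condition", columns="mode", values="fraction")
        if "antisense" in piv.columns and "sense" in piv.columns:
            grp.attrs["antisense_excess"] = (piv["antisense"] - piv["sense"]).to_dict()
    else:
        frac = grp.set_index("mode")["fraction"]
        if "antisense" in frac.index and "sense" in frac.index:
            grp.attrs["antisense_excess"] = float(frac["antisense"] - frac["sense"])
    return grp


# ---------------------------------------------------------------------------
# conservation

def load_track_tsv(path: str | Path, genome: Genome | None = None) -> dict[str, np.ndarray]:
    """3-column TSV (contig, 1-based position, score) -> per-base arrays
    (NaN where the track has no value)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["contig", "position", "score"])
    track: dict[str, np.ndarray] = {}
    for contig, grp in df.groupby("contig"):
        size = (
            genome.length(contig) if genome is not None and contig in genome
            else int(grp["position"].max())
        )
        arr = np.full(size, np.nan)
        arr[grp["position"].to_numpy() - 1] = grp["score"].to_numpy()
        track[contig] = arr
    return track


def load_wiggle(path: str | Path, genome: Genome | None = None) -> dict[str, np.ndarray]:
    """fixedStep wiggle -> per-base arrays (NaN where the track is silent)."""
    chunks: dict[str, list[tuple[int, int, list[float]]]] = {}
    contig, start, step = None, None, 1
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            if line.startswith("fixedStep"):
                if contig is not None and values:
                    chunks.setdefault(contig, []).append((start, step, values))
                fields = dict(
                    kv.split("=") for kv in line.split()[1:] if "=" in kv
                )
                contig = fields["chrom"]
                start = int(fields["start"]) - 1  # wiggle is 1-based
                step = int(fields.get("step", 1))
                values = []
            else:
                values.append(float(line))
    if contig is not None and values:
        chunks.setdefault(contig, []).append((start, step, values))
    track: dict[str, np.ndarray] = {}
    for name, parts in chunks.items():
        if genome is not None and name in genome:
            size = genome.length(name)
        else:
            size = max(s + st * len(v) for s, st, v in parts)
        arr = np.full(size, np.nan)
        for s, st, v in parts:
            idx = s + st * np.arange(len(v))
            arr[idx[idx < size]] = np.asarray(v)[idx < size]
        track[name] = arr
    return track


def sample_background_adenosines(
    genome: Genome,
    n: int,
    rng: np.random.Generator,
    regions: list[tuple[str, int, int]] | None = None,
) -> pd.DataFrame:
    """Randomly chosen adenosines (either strand) for the background
    stratum, optionally restricted to expressed regions."""
    if regions is None:
        regions = [(name, 0, genome.length(name)) for name in genome.names()]
    lengths = np.array([b - a for _, a, b in regions], dtype=float)
    probs = lengths / lengths.sum()
    rows = []
    attempts = 0
    while len(rows) < n and attempts < 200 * n:
        attempts += 1
        ri = int(rng.choice(len(regions), p=probs))
        contig, a, b = regions[ri]
        pos = int(rng.integers(a, b))
        base = genome.contigs[contig][pos]
        strand = "+" if rng.random() < 0.5 else "-"
        want = "A" if strand == "+" else "T"
        if base == want:
            rows.append(dict(contig=contig, pos=pos, strand=strand))
    if len(rows) < n:
        raise RuntimeError("could not sample enough background adenosines")
    return pd.DataFrame(rows)


def conservation_profile(
    sites: pd.DataFrame,
    track: dict[str, np.ndarray],
    genome: Genome,
    window: int = 20,
    background_n: int | None = None,
    seed: int | None = None,
    regions: list[tuple[str, int, int]] | None = None,
) -> pd.DataFrame:
    """Mean conservation per offset (-window..window, site-strand oriented)
    for sites supported by more than one event, sites with a single event,
    and a random-adenosine background of matched size.

    ``sites`` needs an ``n_events`` column for the support strata.  The
    per-stratum n is stored in the result's ``attrs['n']``; empty strata
    are omitted and listed in ``attrs['omitted']``.
    """
    rng = np.random.default_rng(seed)
    strata = {
        "support_gt1": sites[sites["n_events"] > 1],
        "support_eq1": sites[sites["n_events"] == 1],
    }
    n_bg = background_n if background_n is not None else len(sites)
    if n_bg > 0:
        strata["background"] = sample_background_adenosines(
            genome, n_bg, rng, regions
        )
    offsets = np.arange(-window, window + 1)
    data, ns, omitted = {}, {}, []
    for name, df in strata.items():
        if len(df) == 0:
            omitted.append(name)
            continue
        acc = np.zeros(len(offsets))
        cnt = np.zeros(len(offsets))
        for row in df.itertuples(index=False):
            arr = track.get(row.contig)
            if arr is None:
                continue
            sign = 1 if row.strand == "+" else -1
            positions = row.pos + sign * offsets
            valid = (positions >= 0) & (positions < len(arr))
            vals = arr[positions[valid]]
            good = ~np.isnan(vals)
            acc[valid] += np.where(good, vals, 0.0)
            cnt[valid] += good
        with np.errstate(invalid="ignore", divide="ignore"):
            data[name] = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
        ns[name] = len(df)
    profile = pd.DataFrame(data, index=pd.Index(offsets, name="offset"))
    profile.attrs["n"] = ns
    profile.attrs["omitted"] = omitted
    return profile


def evofold_overlap(sites: pd.DataFrame, intervals) -> tuple[int, int, float]:
    """Count sites inside conserved-fold intervals.

    ``intervals``: {contig: IntervalTree} (0-based half-open) or an
    iterable of (contig, start, end).  Returns (n_sites, n_in_folds,
    percentage rounded to 2 decimals).
    """
    if not isinstance(intervals, dict):
        trees: dict[str, IntervalTree] = {}
        for contig, start, end, *_ in intervals:
            trees.setdefault(contig, IntervalTree()).addi(start, end)
        intervals = trees
    n = len(sites)
    n_in = 0
    for row in sites.itertuples(index=False):
        tree = intervals.get(row.contig)
        if tree is not None and tree[row.pos]:
            n_in += 1
    pct = round(100.0 * n_in / n, 2) if n else 0.0
    return n, n_in, pct
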