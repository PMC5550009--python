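"""Differential editing between conditions and the gene-set bootstrap.

Per site and condition pair, the 2x2 table of (G reads, A reads) is tested
with Pearson's chi-square (df=1, no continuity correction), followed by
Benjamini-Hochberg FDR across the tested sites.  A site is called
significantly altered only if additionally both conditions have at least
``min_cov`` informative reads and the editing levels differ by more than
``min_delta`` (absolute).

The gene-set bootstrap compares the pooled editing index of a target gene
set against the null distribution obtained by repeatedly sampling
equally-sized gene sets from a control pool (no replacement within a
draw), with the one-sided add-one p-value
p = (1 + #{null >= observed}) / (B + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def chi2_site_test(g_a: int, a_a: int, g_b: int, a_b: int) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 table [[g_a, a_a], [g_b, a_b]].

    df = 1, no continuity correction.  Raises ValueError on a zero margin
    (the test is undefined there; callers skip such sites).
    """
    for c in (g_a, a_a, g_b, a_b):
        if c < 0:
            raise ValueError("negative count")
    n = g_a + a_a + g_b + a_b
    r1, r2 = g_a + a_a, g_b + a_b
    c1, c2 = g_a + g_b, a_a + a_b
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("zero margin: chi-square test undefined")
    chi2 = n * (g_a * a_b - a_a * g_b) ** 2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment and rejection mask at level q.

    NaN p-values are excluded from the family (m) and returned as NaN /
    not rejected.
    """
    p = np.asarray(pvalues, dtype=float)
    adjusted = np.full(p.shape, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    if ok.sum():
        rej, adj, _, _ = multipletests(p[ok], alpha=q, method="fdr_bh")
        adjusted[ok] = adj
        reject[ok] = rej
    return adjusted, reject


def pool_by_condition(
    pileups: pd.DataFrame, sample_conditions: dict[str, str] | None = None
) -> pd.DataFrame:
    """Sum pileup counts within each condition.

    Without ``sample_conditions`` the sample column is taken to already
    hold condition labels.
    """
    df = pileups.copy()
    if sample_conditions is not None:
        df["condition"] = df["sample"].map(sample_conditions)
        if df["condition"].isna().any():
            missing = sorted(df.loc[df["condition"].isna(), "sample"].unique())
            raise KeyError(f"samples without a condition: {missing}")
    else:
        df["condition"] = df["sample"]
    out = (
        df.groupby(["contig", "pos", "strand", "condition"], as_index=False)[
            ["a_count", "g_count"]
        ].sum()
    )
    out["coverage"] = out["a_count"] + out["g_count"]
    out["level"] = np.where(
        out["coverage"] > 0, out["g_count"] / out["coverage"].clip(lower=1), np.nan
    )
    return out


DIFF_COLUMNS = [
    "contig", "pos", "strand", "condition_a", "condition_b",
    "g_a", "a_a", "g_b", "a_b", "level_a", "level_b", "delta",
    "chi2", "p", "q", "coverage_ok", "delta_ok", "significant",
]


def differential_sites(
    pileups: pd.DataFrame,
    sample_conditions: dict[str, str] | None = None,
    pairs: list[tuple[str, str]] | None = None,
    min_cov: int = 50,
    min_delta: float = 0.20,
    q: float = 0.05,
) -> pd.DataFrame:
    """Pairwise differential editing across conditions.

    For each condition pair, every site with both margins positive is
    chi-square tested and BH-adjusted within that pair.  Flags:
    coverage_ok (>= min_cov informative reads in both conditions),
    delta_ok (|level_b - level_a| > min_delta), significant (q-value <= q
    and both flags).
    """
    pooled = pool_by_condition(pileups, sample_conditions)
    conditions = sorted(pooled["condition"].unique())
    if len(conditions) < 2:
        raise ValueError("need at least two conditions")
    if pairs is None:
        pairs = list(combinations(conditions, 2))
    wide = pooled.pivot_table(
        index=["contig", "pos", "strand"],
        columns="condition",
        values=["a_count", "g_count"],
        fill_value=0,
        aggfunc="sum",
    )
    frames = []
    for ca, cb in pairs:
        ga = wide[("g_count", ca)].to_numpy(dtype=int)
        aa = wide[("a_count", ca)].to_numpy(dtype=int)
        gb = wide[("g_count", cb)].to_numpy(dtype=int)
        ab = wide[("a_count", cb)].to_numpy(dtype=int)
        chi2_vals = np.full(len(ga), np.nan)
        p_vals = np.full(len(ga), np.nan)
        for i in range(len(ga)):
            try:
                chi2_vals[i], p_vals[i] = chi2_site_test(ga[i], aa[i], gb[i], ab[i])
            except ValueError:
                continue
        q_vals, reject = bh_fdr(p_vals, q)
        cov_a, cov_b = ga + aa, gb + ab
        level_a = np.where(cov_a > 0, ga / np.maximum(cov_a, 1), np.nan)
        level_b = np.where(cov_b > 0, gb / np.maximum(cov_b, 1), np.nan)
        delta = level_b - level_a
        coverage_ok = (cov_a >= min_cov) & (cov_b >= min_cov)
        delta_ok = np.abs(delta) > min_delta
        significant = reject & coverage_ok & delta_ok
        idx = wide.index.to_frame(index=False)
        df = pd.DataFrame(
            dict(
                contig=idx["contig"], pos=idx["pos"], strand=idx["strand"],
                condition_a=ca, condition_b=cb,
                g_a=ga, a_a=aa, g_b=gb, a_b=ab,
                level_a=level_a, level_b=level_b, delta=delta,
                chi2=chi2_vals, p=p_vals, q=q_vals,
                coverage_ok=coverage_ok, delta_ok=delta_ok,
                significant=significant,
            )
        )
        frames.append(df)
    return pd.concat(frames, ignore_index=True)[DIFF_COLUMNS]


@dataclass
class BootstrapResult:
    observed: float
    null: np.ndarray
    p: float

    @property
    def B(self) -> int:
        return len(self.null)


def geneset_editing_bootstrap(
    target_genes,
    pool_genes,
    gene_counts: pd.DataFrame,
    B: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BootstrapResult:
    """Bootstrap test of a gene set's editing index against a control pool.

    ``gene_counts`` has one row per gene (gene_id, g_count, ag_count);
    the statistic is the pooled editing index of the set.  Null sets of the
    target's size are drawn from ``pool_genes`` without replacement, B
    times.  One-sided: p small when the target's index exceeds the null.
    """
    target = list(target_genes)
    pool = list(pool_genes)
    if not target:
        raise ValueError("target gene set is empty")
    if len(pool) < len(target):
        raise ValueError(
            f"control pool ({len(pool)}) smaller than target set ({len(target)})"
        )
    counts = gene_counts.set_index("gene_id")
    missing = [g for g in target if g not in counts.index]
    if missing:
        raise KeyError(f"target genes without counts: {missing[:5]}")
    pool_in = [g for g in pool if g in counts.index]
    if len(pool_in) < len(target):
        raise ValueError("control pool has too few genes with counts")
    t_g = counts.loc[target, "g_count"].to_numpy(dtype=float)
    t_ag = counts.loc[target, "ag_count"].to_numpy(dtype=float)
    if t_ag.sum() == 0:
        raise ValueError("target gene set has zero informative coverage")
    observed = float(t_g.sum() / t_ag.sum())
    p_g = counts.loc[pool_in, "g_count"].to_numpy(dtype=float)
    p_ag = counts.loc[pool_in, "ag_count"].to_numpy(dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    k, n = len(target), len(pool_in)
    null = np.empty(B, dtype=float)
    for b in range(B):
        idx = rng.choice(n, size=k, replace=False)
        denom = p_ag[idx].sum()
        null[b] = p_g[idx].sum() / denom if denom > 0 else 0.0
    p = (1 + int(np.sum(null >= observed))) / (B + 1)
    return BootstrapResult(observed=observed, null=null, p=float(p))


def top_expressed_pool(
    expression: pd.DataFrame, fraction: float = 0.60
) -> list[str]:
    """Control pool: the top ``fraction`` of genes ranked by mean expression.

    ``expression`` needs a gene_id column; every other numeric column is a
    per-sample count.
    """
    counts = expression.set_index("gene_id").select_dtypes("number")
    means = counts.mean(axis=1).sort_values(ascending=False, kind="stable")
    k = max(int(round(fraction * len(means))), 1)
    return list(means.index[:k])


def ks_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (D statistic and p-value)."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values on each side")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)
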