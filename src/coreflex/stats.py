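"""Selection statistics: enrichment, dN/dS, G scores, and test suite.

The headline statistics are:

* compartment enrichment — the raw count ratio core_n/flex_n (the printed
  "odds ratio"), the length-normalised rate ratio, and an exact two-tailed
  binomial test of the core count against the length-based expectation
  p0 = L_core / (L_core + L_flex);
* dN/dS — the nonsynonymous/synonymous mutation count ratio divided by the
  genome-wide nonsynonymous-to-synonymous site ratio rho (~3.22 for the
  ancestral genome analysed here);
* the per-gene parallelism G score, G_i = 2 O_i ln(O_i / E_i), where O_i
  is the number of independent nonsynonymous mutations observed in
  non-hypermutator lineages and E_i = T * L_i / sum(L) the length-
  proportional expectation (G_i = 0 when O_i = 0, the x ln x limit).

Nonparametric and parametric comparisons (Spearman, Mann-Whitney, Wilcoxon
signed-rank, Welch's t, Fisher's exact, bootstrap median CIs) are thin,
explicitly-parameterised wrappers around scipy.stats, with exact small-n
p-values obtained by complete enumeration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CompartmentCounts",
    "EnrichmentResult",
    "DnDsResult",
    "GeneSelectionStats",
    "RankTestResult",
    "MedianCI",
    "enrichment_test",
    "dnds_ratio",
    "gscores",
    "spearman_correlation",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "welch_t",
    "fisher_exact_one_tailed",
    "bootstrap_median_ci",
]

DEFAULT_SITE_RATIO = 3.22  # genome-wide nonsyn:syn site ratio for the ancestor


@dataclass(frozen=True)
class CompartmentCounts:
    core_n: int
    flex_n: int
    L_core: int
    L_flex: int

    def __post_init__(self) -> None:
        if self.core_n < 0 or self.flex_n < 0:
            raise ValueError("counts must be non-negative")
        if self.L_core <= 0 or self.L_flex <= 0:
            raise ValueError("compartment lengths must be positive")


@dataclass(frozen=True)
class EnrichmentResult:
    odds_ratio: float  # core_n / flex_n; nan when flex_n == 0
    odds_ratio_defined: bool
    rate_ratio: float  # (core_n/L_core) / (flex_n/L_flex)
    p0: float  # expected core fraction from lengths
    p_value: float  # exact two-tailed binomial
    core_n: int
    flex_n: int


@dataclass(frozen=True)
class DnDsResult:
    nonsyn_n: float
    syn_n: float
    site_ratio: float
    dnds: float


@dataclass(frozen=True)
class GeneSelectionStats:
    gene_id: str
    L: int
    O: int
    E: float
    G: float


@dataclass(frozen=True)
class RankTestResult:
    method: str
    statistic: float
    p_value: float
    sidedness: str
    n: tuple[int, ...]
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError("p out of [0,1]")


@dataclass(frozen=True)
class MedianCI:
    median: float
    ci_low: float
    ci_high: float
    level: float
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.median <= self.ci_high):
            raise ValueError("CI does not bracket the median")


# ---------------------------------------------------------------------------
# enrichment / dN/dS / G scores

def enrichment_test(counts: CompartmentCounts) -> EnrichmentResult:
    """Core-vs-flexible enrichment with an exact two-tailed binomial test.

    The two-sided p follows the minimum-likelihood rule (sum of outcome
    probabilities no larger than the observed one), as implemented by
    scipy's exact binomial test.
    """
    n = counts.core_n + counts.flex_n
    if n == 0:
        raise ValueError("no mutations to test")
    p0 = counts.L_core / (counts.L_core + counts.L_flex)
    p_value = sps.binomtest(counts.core_n, n, p0, alternative="two-sided").pvalue
    defined = counts.flex_n > 0
    odds = counts.core_n / counts.flex_n if defined else float("nan")
    rate_core = counts.core_n / counts.L_core
    rate_flex = counts.flex_n / counts.L_flex
    rate_ratio = rate_core / rate_flex if rate_flex > 0 else float("inf")
    return EnrichmentResult(
        odds_ratio=odds,
        odds_ratio_defined=defined,
        rate_ratio=rate_ratio,
        p0=p0,
        p_value=float(p_value),
        core_n=counts.core_n,
        flex_n=counts.flex_n,
    )


def dnds_ratio(
    nonsyn_n: float, syn_n: float, site_ratio: float = DEFAULT_SITE_RATIO
) -> DnDsResult:
    """dN/dS from mutation counts: (nonsyn/syn) / site_ratio."""
    if syn_n <= 0:
        raise ValueError("dN/dS undefined for syn_n = 0")
    if site_ratio <= 0:
        raise ValueError("site_ratio must be positive")
    if nonsyn_n < 0:
        raise ValueError("counts must be non-negative")
    return DnDsResult(nonsyn_n, syn_n, site_ratio, (nonsyn_n / syn_n) / site_ratio)


def gscores(genes: list[tuple[str, int, int]]) -> list[GeneSelectionStats]:
    """Per-gene parallelism G scores from (gene_id, L_i, O_i) triples.

    E_i = T * L_i / sum(L) with T = sum(O_i); G_i = 2 O_i ln(O_i/E_i),
    defined as 0 when O_i = 0.
    """
    if not genes:
        return []
    for gid, L, O in genes:
        if L <= 0:
            raise ValueError(f"{gid}: L must be positive")
        if O < 0:
            raise ValueError(f"{gid}: negative count")
    total_L = sum(L for _, L, _ in genes)
    T = sum(O for _, _, O in genes)
    out = []
    for gid, L, O in genes:
        E = T * L / total_L
        G = 0.0 if O == 0 else 2.0 * O * math.log(O / E)
        out.append(GeneSelectionStats(gene_id=gid, L=L, O=O, E=E, G=G))
    return out


def gscores_frame(genes: pd.DataFrame) -> pd.DataFrame:
    """G scores as a tidy frame from columns gene_id, L, O."""
    rows = gscores(list(genes[["gene_id", "L", "O"]].itertuples(index=False, name=None)))
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# rank / parametric tests

SPEARMAN_EXACT_MAX_N = 8
MANN_WHITNEY_EXACT_MAX_PRODUCT = 400
WILCOXON_EXACT_MAX_N = 15


def spearman_correlation(x, y) -> RankTestResult:
    """Spearman rank correlation with average ranks for ties.

    Exact permutation p for n <= 8 (full enumeration of pairings);
    t-distribution approximation otherwise.  Two-tailed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    r = float(sps.spearmanr(x, y).statistic)
    n = len(x)
    if n <= SPEARMAN_EXACT_MAX_N:
        def stat(xp):
            return sps.spearmanr(xp, y).statistic

        res = sps.permutation_test(
            (x,),
            stat,
            permutation_type="pairings",
            alternative="two-sided",
            n_resamples=math.factorial(n),
        )
        p = float(res.pvalue)
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return RankTestResult("spearman", r, p, "two-sided", (n,))


def mann_whitney(group_a, group_b, alternative: str = "two-sided") -> RankTestResult:
    """Mann-Whitney U for group_a, ties counted as 1/2.

    Exact enumeration when n_a * n_b <= 400 (complete relabelling of the
    pooled sample); otherwise the normal approximation with tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    # U by pair counting via the rank formula (ties = 1/2)
    u_res = sps.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    U = float(u_res.statistic)
    if min(len(a), len(b)) >= 2 and len(a) * len(b) <= MANN_WHITNEY_EXACT_MAX_PRODUCT:
        def stat(xa, xb):
            return sps.mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic").statistic

        res = sps.permutation_test(
            (a, b),
            stat,
            permutation_type="independent",
            alternative=alternative,
            n_resamples=math.comb(len(a) + len(b), len(a)),
        )
        p = float(res.pvalue)
    else:
        # asymptotic with tie correction; scipy switches to exact for small
        # untied single-observation groups on its own
        method = "auto" if min(len(a), len(b)) < 2 else "asymptotic"
        p = float(sps.mannwhitneyu(a, b, alternative=alternative, method=method).pvalue)
    return RankTestResult(
        "mann_whitney", U, p, alternative, (len(a), len(b)), {"U_a": U, "U_b": len(a) * len(b) - U}
    )


def wilcoxon_signed_rank(
    paired_a, paired_b, alternative: str = "two-sided"
) -> RankTestResult:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; tied absolute differences share average
    ranks.  The statistic W is the smaller of the positive/negative rank
    sums.  Exact p by complete sign enumeration for n <= 15 after zero
    removal; normal approximation beyond.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    W = min(w_plus, w_minus)
    if n <= WILCOXON_EXACT_MAX_N:
        def stat(x):
            return sps.rankdata(np.abs(x))[x > 0].sum()

        res = sps.permutation_test(
            (d,),
            stat,
            permutation_type="samples",
            alternative=alternative,
            n_resamples=1 << n,
        )
        p = float(res.pvalue)
    else:
        res = sps.wilcoxon(d, alternative=alternative, method="approx")
        p = float(res.pvalue)
    return RankTestResult(
        "wilcoxon_signed_rank", W, p, alternative, (n,),
        {"w_plus": w_plus, "w_minus": w_minus},
    )


def welch_t(group_a, group_b, alternative: str = "two-sided") -> RankTestResult:
    """Welch's unequal-variance t test with Welch-Satterthwaite d.f."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        raise ValueError("zero variance in both groups with equal means")
    res = sps.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return RankTestResult(
        "welch_t", float(res.statistic), float(res.pvalue), alternative,
        (len(a), len(b)), {"df": float(res.df)},
    )


def fisher_exact_one_tailed(table_2x2, alternative: str = "greater") -> RankTestResult:
    """One-tailed Fisher's exact (hypergeometric) test on a 2x2 table.

    A zero row or column margin makes the table degenerate: p = 1, flagged.
    """
    t = np.asarray(table_2x2, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    degenerate = (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any()
    if degenerate:
        return RankTestResult(
            "fisher_exact", float("nan"), 1.0, alternative,
            tuple(int(v) for v in t.ravel()), {"degenerate": True},
        )
    odds, p = sps.fisher_exact(t, alternative=alternative)
    return RankTestResult(
        "fisher_exact", float(odds), float(p), alternative,
        tuple(int(v) for v in t.ravel()), {"degenerate": False},
    )


def binomial_two_tailed(k: int, n: int, p0: float) -> RankTestResult:
    """Exact two-tailed binomial test (minimum-likelihood rule)."""
    res = sps.binomtest(k, n, p0, alternative="two-sided")
    return RankTestResult("binomial", float(k), float(res.pvalue), "two-sided", (n,), {"p0": p0})


def bootstrap_median_ci(
    values, n_boot: int = 10_000, seed: int = 0, level: float = 0.95
) -> MedianCI:
    """Percentile bootstrap confidence interval around the median."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable intervals", stacklevel=2)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(v), size=(n_boot, len(v)))
    meds = np.median(v[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(meds, [alpha, 1.0 - alpha])
    med = float(np.median(v))
    return MedianCI(
        median=med,
        ci_low=float(min(lo, med)),
        ci_high=float(max(hi, med)),
        level=level,
        n_boot=n_boot,
        seed=seed,
    )
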