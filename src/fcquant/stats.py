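"""Two-group comparison statistics, reported the way the source experiments
were: group mean ± SD/SEM, percent reduction of the test group relative to
control, an unpaired t-test (pooled-variance by default, Welch optional) and
a Mann-Whitney U test (exact by enumeration for small samples, tie-corrected
normal approximation otherwise). All p-values are two-sided; no
multiple-testing correction is applied.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .quantify import CellRecord

__all__ = [
    "GroupSummary",
    "TTestResult",
    "MannWhitneyResult",
    "ComparisonResult",
    "summarize",
    "percent_reduction",
    "unpaired_t_test",
    "mann_whitney_u",
    "compare_groups",
    "CELL_METRICS",
]

#: Per-cell metrics a two-group comparison may target.
CELL_METRICS = ("fc_count", "mean_fc_area_um2", "total_fc_area_um2")

#: Largest combined sample size for which the Mann-Whitney p is computed by
#: full enumeration of rank assignments.
EXACT_MWU_MAX_N = 12


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float

    @property
    def sem(self) -> float:
        return self.sd / math.sqrt(self.n)


def summarize(values, label: str = "") -> GroupSummary:
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("group summaries need n >= 2")
    return GroupSummary(label, int(v.size), float(v.mean()),
                        float(v.std(ddof=1)))


def percent_reduction(control_mean: float, test_mean: float) -> float:
    """100 x (1 - test/control); negative values indicate an increase."""
    if not (control_mean > 0):
        raise ValueError(f"control mean must be > 0, got {control_mean}")
    return 100.0 - 100.0 * test_mean / control_mean


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    variant: str


def unpaired_t_test(group_a, group_b, variant: str = "student") -> TTestResult:
    """Two-sided unpaired t-test.

    ``variant="student"`` pools the variances; ``"welch"`` does not.
    Two zero-variance groups with equal means give t = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    pooled = variant == "student"
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            df = a.size + b.size - 2 if pooled else float(a.size + b.size - 2)
            return TTestResult(0.0, float(df), 1.0, variant)
        return TTestResult(math.copysign(math.inf, a.mean() - b.mean()),
                           float(a.size + b.size - 2), 0.0, variant)
    res = sps.ttest_ind(a, b, equal_var=pooled)
    df = float(res.df)
    return TTestResult(float(res.statistic), df, float(res.pvalue), variant)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float      # min(U_a, U_b), midrank ties
    p: float
    method: str   # "exact" or "normal"


def _u_min_from_ranks(rank_sum_a: float, n_a: int, n_b: int) -> float:
    u_a = rank_sum_a - n_a * (n_a + 1) / 2.0
    return min(u_a, n_a * n_b - u_a)


def mann_whitney_u(group_a, group_b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U with midrank ties.

    U = min(U_a, U_b). For combined n <= 12 the p-value is the exact
    permutation probability P(min-U <= observed) over all rank
    assignments; otherwise a tie-corrected normal approximation with
    continuity correction is used.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs n >= 1")
    n_a, n_b = int(a.size), int(b.size)
    n = n_a + n_b
    ranks = sps.rankdata(np.concatenate([a, b]))
    u_obs = _u_min_from_ranks(float(ranks[:n_a].sum()), n_a, n_b)

    if n <= EXACT_MWU_MAX_N:
        hits = total = 0
        for subset in itertools.combinations(range(n), n_a):
            u = _u_min_from_ranks(float(ranks[list(subset)].sum()), n_a, n_b)
            total += 1
            if u <= u_obs + 1e-9:
                hits += 1
        return MannWhitneyResult(u_obs, hits / total, "exact")

    mu = n_a * n_b / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum()) / (n * (n - 1))
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:  # all values identical
        return MannWhitneyResult(u_obs, 1.0, "normal")
    z = (u_obs - mu + 0.5) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * sps.norm.cdf(z))
    return MannWhitneyResult(u_obs, p, "normal")


@dataclass(frozen=True)
class ComparisonResult:
    metric: str
    percent_reduction: float
    t_statistic: float
    degrees_of_freedom: float
    p_value_t: float
    u_statistic: float
    p_value_u: float
    test_used: str
    reduction_se_bootstrap: float | None = None  # only when bootstrapped


def _bootstrap_reduction_se(control: np.ndarray, test: np.ndarray,
                            n_boot: int, seed: int) -> float:
    """Bootstrap SE of the percent reduction, resampling cells with
    replacement within each group."""
    rng = np.random.default_rng(seed)
    reds = np.empty(n_boot)
    for i in range(n_boot):
        c = control[rng.integers(0, control.size, control.size)].mean()
        t = test[rng.integers(0, test.size, test.size)].mean()
        reds[i] = 100.0 * (1.0 - t / c) if c > 0 else np.nan
    return float(np.nanstd(reds, ddof=1))


def compare_groups(control: list[CellRecord], test: list[CellRecord],
                   metric: str, t_variant: str = "student",
                   n_boot: int = 0, seed: int = 0
                   ) -> tuple[GroupSummary, GroupSummary, ComparisonResult]:
    """Compare a per-cell metric between control and test cells.

    Returns the two group summaries and a :class:`ComparisonResult` with
    the percent reduction of the group means, the unpaired t-test and the
    Mann-Whitney U test. Cells with an undefined metric value (NaN, e.g.
    mean contact area of a contact-free cell) are dropped. ``n_boot > 0``
    adds a bootstrap standard error of the reduction (resampling cells).
    """
    if metric not in CELL_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {CELL_METRICS}")
    c = np.asarray([getattr(r, metric) for r in control], dtype=np.float64)
    t = np.asarray([getattr(r, metric) for r in test], dtype=np.float64)
    c = c[~np.isnan(c)]
    t = t[~np.isnan(t)]
    if c.size < 2 or t.size < 2:
        raise ValueError("each group needs >= 2 cells with a defined metric")
    sc = summarize(c, "control")
    st = summarize(t, "test")
    tt = unpaired_t_test(c, t, t_variant)
    mw = mann_whitney_u(c, t)
    boot = (_bootstrap_reduction_se(c, t, n_boot, seed)
            if n_boot > 0 else None)
    result = ComparisonResult(
        metric=metric,
        percent_reduction=percent_reduction(sc.mean, st.mean),
        t_statistic=tt.t,
        degrees_of_freedom=tt.df,
        p_value_t=tt.p,
        u_statistic=mw.u,
        p_value_u=mw.p,
        test_used=f"t:{tt.variant}+mwu:{mw.method}",
        reduction_se_bootstrap=boot,
    )
    return sc, st, result
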