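"""Statistical procedures and behavioral metrics for mating-duration assays.

Implements the full analysis battery applied to every assay: the one-hour
inclusion filter, percent-reduction effect sizes, the pooled-variance
Student's t test, Lilliefors-corrected Kolmogorov-Smirnov normality and
lognormality checks, Kruskal-Wallis with Dunn's multiple-comparison post
hoc, bootstrap estimation statistics (mean difference with CI), the
star/hash significance annotation, courtship-index and locomotion metrics,
and CaLexA fluorescence normalisation, plus an orchestrator that runs a
whole comparison end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "ComparisonResult",
    "EstimationResult",
    "MultiGroupResult",
    "TTestResult",
    "DunnComparison",
    "filter_within_window",
    "percent_reduction",
    "students_t",
    "ks_normality",
    "kruskal_wallis",
    "dunns_multiple_comparison",
    "bootstrap_mean_difference",
    "significance_annotation",
    "courtship_index",
    "locomotion_velocity",
    "normalize_fluorescence",
    "compare_experiment",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False

    def __iter__(self):  # allows t, df, p = students_t(a, b)
        return iter((self.t, self.df, self.p))


@dataclass(frozen=True)
class ComparisonResult:
    """Two-group comparison: effect size, test statistics and annotation."""

    group_labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    sems: tuple[float, float]
    percent_reduction: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    stars: str
    normality_p: tuple[float, float]


@dataclass(frozen=True)
class EstimationResult:
    """Bootstrap estimation statistics for an unpaired mean difference."""

    mean_difference: float
    ci_low: float
    ci_high: float
    ci_level: float
    n_resamples: int
    resample_distribution: dict
    method: str
    seed: int


@dataclass(frozen=True)
class DunnComparison:
    pair: tuple[str, str]
    rank_mean_difference: float
    z: float
    p_adjusted: float
    hash_mark: bool


@dataclass(frozen=True)
class MultiGroupResult:
    kw_H: float
    kw_p: float
    comparisons: tuple[DunnComparison, ...]


# ---------------------------------------------------------------------------
# filtering and simple metrics


def filter_within_window(table: pd.DataFrame, window: float = 3600.0) -> pd.DataFrame:
    """Keep males that mated within the window (latency <= window, inclusive).

    Returns the surviving rows in their original order with the ``included``
    flag set; idempotent by construction.
    """
    if "copulation_latency_s" not in table.columns:
        raise KeyError("table lacks required column 'copulation_latency_s'")
    out = table.loc[table["copulation_latency_s"] <= window].copy()
    out["included"] = True
    return out


def percent_reduction(reference, comparison) -> float:
    """(mean_ref - mean_cmp) / mean_ref * 100.

    The reference group is the naive condition throughout the package, so a
    positive value means the comparison group mated for a shorter time.
    """
    ref = np.asarray(reference, dtype=float)
    cmp_ = np.asarray(comparison, dtype=float)
    if ref.size == 0 or cmp_.size == 0:
        raise ValueError("both groups must be non-empty")
    m = ref.mean()
    if m <= 0:
        raise ValueError(f"reference mean must be > 0, got {m}")
    return float((m - cmp_.mean()) / m * 100.0)


def courtship_index(
    courtship_time_s: float,
    observation_window_s: float = 600.0,
    time_to_mate_s: float | None = None,
) -> float:
    """Fraction of the observation window spent courting, truncated at mating onset."""
    window = observation_window_s
    if time_to_mate_s is not None:
        window = min(window, time_to_mate_s)
    if window <= 0:
        raise ValueError("effective observation window must be > 0")
    if courtship_time_s < 0 or courtship_time_s > window:
        raise ValueError(
            f"courtship time {courtship_time_s} outside [0, {window}] effective window"
        )
    return courtship_time_s / window


def locomotion_velocity(distance_mm: float, time_s: float) -> float:
    """Distance walked divided by time, in mm/s."""
    if time_s <= 0:
        raise ValueError(f"time must be > 0, got {time_s}")
    if distance_mm < 0:
        raise ValueError(f"distance must be >= 0, got {distance_mm}")
    return distance_mm / time_s


def normalize_fluorescence(gfp, autofluorescence):
    """CaLexA GFP normalised to autofluorescence (ratio of ROI intensities)."""
    auto = np.asarray(autofluorescence, dtype=float)
    if np.any(auto <= 0):
        raise ValueError("autofluorescence must be > 0")
    out = np.asarray(gfp, dtype=float) / auto
    return out.item() if np.ndim(gfp) == 0 and np.ndim(autofluorescence) == 0 else out


# ---------------------------------------------------------------------------
# hypothesis tests


def students_t(a, b) -> TTestResult:
    """Classic two-sample pooled-variance Student's t test, two-sided.

    df = n_a + n_b - 2.  Degenerate zero-variance inputs follow the
    conventions: equal means -> t = 0, p = 1; unequal means -> p = 0 with the
    ``degenerate`` flag set.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    na, nb = x.size, y.size
    df = na + nb - 2
    pooled = ((na - 1) * x.var(ddof=1) + (nb - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if pooled == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, df, 1.0, degenerate=True)
        return TTestResult(math.copysign(math.inf, diff), df, 0.0, degenerate=True)
    t = diff / math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(min(p, 1.0)))


def welch_t(a, b) -> TTestResult:
    """Welch's unequal-variance alternative, for when pooling is unwarranted."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    t, p = sps.ttest_ind(x, y, equal_var=False)
    va, vb = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
    if va + vb == 0:
        return students_t(x, y)
    df = (va + vb) ** 2 / (va**2 / (x.size - 1) + vb**2 / (y.size - 1))
    return TTestResult(float(t), float(df), float(p))


def ks_normality(
    values,
    mode: Literal["normal", "lognormal"] = "normal",
    corrected: bool = True,
) -> tuple[float, float]:
    """Kolmogorov-Smirnov test of (log)normality with estimated parameters.

    By default applies the Lilliefors correction, appropriate when the normal
    law's mean and sd are estimated from the sample itself; ``corrected=False``
    gives the naive fully-specified KS test (anticonservative in this
    setting).  ``mode='lognormal'`` tests the log-transformed values and
    requires strictly positive input.  Returns (D, p).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("need n >= 5 for the normality test")
    if mode == "lognormal":
        if np.any(x <= 0):
            raise ValueError("lognormality mode requires strictly positive values")
        x = np.log(x)
    elif mode != "normal":
        raise ValueError(f"unknown mode {mode!r}")
    if x.std(ddof=1) == 0:
        raise ValueError("sample is constant; normality is undefined")
    if corrected:
        d, p = lilliefors(x, dist="norm", pvalmethod="table")
    else:
        d, p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return float(d), float(p)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Rank-based H with tie correction; p from chi-square with k-1 df.

    All-identical values return (0, 1) rather than erroring.
    """
    _check_groups(groups)
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*[np.asarray(g, dtype=float) for g in groups])
    return float(h), float(p)


def _check_groups(groups) -> None:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    sizes = [len(g) for g in groups]
    if any(s < 1 for s in sizes):
        raise ValueError("each group needs n >= 1")
    if sum(sizes) < 3:
        raise ValueError("need total n >= 3")


def dunns_multiple_comparison(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    control: int | None = 0,
) -> MultiGroupResult:
    """Kruskal-Wallis followed by Dunn's multiple comparison test.

    Pairwise z = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T)(1/n_i + 1/n_j)]
    on the joint ranks, with the tie term T = sum(t^3 - t)/(12(N-1)).
    Two-sided normal p per pair, Bonferroni-adjusted over the comparisons
    performed: control-vs-all when ``control`` is a group index (the
    default, index 0), all pairs when ``control`` is None.  ``hash_mark``
    flags adjusted p < 0.05, the paper-style number-sign annotation.
    """
    _check_groups(groups)
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels length must match number of groups")
    h, p_kw = kruskal_wallis(arrays)

    flat = np.concatenate(arrays)
    n_total = flat.size
    ranks = sps.rankdata(flat)
    sizes = np.array([a.size for a in arrays])
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array(
        [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(k)]
    )
    _, counts = np.unique(flat, return_counts=True)
    tie_term = float((counts**3 - counts).sum()) / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    var_factor = n_total * (n_total + 1) / 12.0 - tie_term

    if control is None:
        pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    else:
        if not (0 <= control < k):
            raise ValueError(f"control index {control} out of range")
        pairs = [(control, j) for j in range(k) if j != control]
    m = len(pairs)

    comps = []
    for i, j in pairs:
        diff = mean_ranks[i] - mean_ranks[j]
        denom = math.sqrt(var_factor * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = diff / denom if denom > 0 else 0.0
        p_pair = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p_pair * m)
        comps.append(
            DunnComparison(
                pair=(labels[i], labels[j]),
                rank_mean_difference=float(diff),
                z=float(z),
                p_adjusted=float(p_adj),
                hash_mark=bool(p_adj < 0.05),
            )
        )
    return MultiGroupResult(kw_H=h, kw_p=p_kw, comparisons=tuple(comps))


# ---------------------------------------------------------------------------
# estimation statistics


def bootstrap_mean_difference(
    a,
    b,
    n_resamples: int = 5000,
    ci_level: float = 0.95,
    method: Literal["percentile", "bca"] = "percentile",
    seed: int = 0,
) -> EstimationResult:
    """Unpaired mean difference (b - a) with a bootstrap confidence interval.

    Groups are resampled independently with replacement; the CI is taken
    from the resample distribution by the percentile method (default) or
    with bias-correction and acceleration (BCa, jackknife acceleration).
    Deterministic for a fixed seed.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    if n_resamples < 100:
        raise ValueError(f"n_resamples must be >= 100, got {n_resamples}")
    if not (0 < ci_level < 1):
        raise ValueError("ci_level must be on (0, 1)")
    rng = np.random.default_rng(seed)
    observed = float(y.mean() - x.mean())
    bx = rng.choice(x, size=(n_resamples, x.size), replace=True).mean(axis=1)
    by = rng.choice(y, size=(n_resamples, y.size), replace=True).mean(axis=1)
    dist = by - bx
    alpha = 1.0 - ci_level
    if method == "percentile":
        lo, hi = np.quantile(dist, [alpha / 2.0, 1.0 - alpha / 2.0])
    elif method == "bca":
        lo, hi = _bca_interval(x, y, dist, observed, alpha)
    else:
        raise ValueError(f"unknown method {method!r}")
    summary = {
        "median": float(np.median(dist)),
        "sd": float(dist.std(ddof=1)),
        "q025": float(np.quantile(dist, 0.025)),
        "q975": float(np.quantile(dist, 0.975)),
    }
    return EstimationResult(
        mean_difference=observed,
        ci_low=float(lo),
        ci_high=float(hi),
        ci_level=ci_level,
        n_resamples=n_resamples,
        resample_distribution=summary,
        method=method,
        seed=seed,
    )


def _bca_interval(x, y, dist, observed, alpha):
    # bias correction from the resample distribution
    prop = np.mean(dist < observed)
    prop = min(max(prop, 1.0 / (dist.size + 1)), 1.0 - 1.0 / (dist.size + 1))
    z0 = sps.norm.ppf(prop)
    # acceleration from a leave-one-out jackknife over both groups
    jack = []
    for i in range(x.size):
        jack.append(y.mean() - np.delete(x, i).mean())
    for i in range(y.size):
        jack.append(np.delete(y, i).mean() - x.mean())
    jack = np.asarray(jack)
    dev = jack.mean() - jack
    denom = 6.0 * (dev**2).sum() ** 1.5
    acc = (dev**3).sum() / denom if denom > 0 else 0.0
    z_lo, z_hi = sps.norm.ppf([alpha / 2.0, 1.0 - alpha / 2.0])
    def adj(z):
        q = z0 + (z0 + z) / (1.0 - acc * (z0 + z))
        return sps.norm.cdf(q)
    return tuple(np.quantile(dist, [adj(z_lo), adj(z_hi)]))


def significance_annotation(p: float) -> str:
    """Star annotation with the conventional strict thresholds (0.05/0.01/0.001)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be on [0, 1], got {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# end-to-end comparison


def compare_experiment(
    table: pd.DataFrame,
    metric: str = "mating_duration_s",
    group_by: Sequence[str] = ("condition",),
    groups: Sequence[str] | None = None,
    reference: str | None = None,
    window: float | None = 3600.0,
    n_resamples: int = 5000,
    seed: int = 0,
):
    """Run one comparison end to end: filter, normality, test, bootstrap, stars.

    Groups are formed from ``group_by`` (labels joined by '/'); ``groups``
    restricts and orders them, with the first (or ``reference``) treated as
    the reference for the percent-reduction effect size.  Two groups get a
    Student's t plus bootstrap estimation; more than two get Kruskal-Wallis
    with Dunn's control-vs-all post hoc against the reference.  Returns
    (ComparisonResult, EstimationResult) or (ComparisonResult of the first
    pair, EstimationResult, MultiGroupResult).
    """
    if metric not in table.columns:
        raise KeyError(f"metric column {metric!r} missing from table")
    data = table
    if window is not None and "copulation_latency_s" in table.columns:
        data = filter_within_window(table, window)
    key = (
        data[list(group_by)].astype(str).agg("/".join, axis=1)
        if len(group_by) > 1
        else data[group_by[0]].astype(str)
    )
    present = list(dict.fromkeys(key))
    wanted = list(groups) if groups is not None else present
    missing = [g for g in wanted if g not in present]
    if missing:
        raise ValueError(f"groups not present after filtering: {missing}")
    if reference is None:
        reference = wanted[0]
    ordered = [reference] + [g for g in wanted if g != reference]
    samples = [data.loc[key == g, metric].to_numpy(dtype=float) for g in ordered]

    norm_p = []
    for s in samples[:2]:
        try:
            norm_p.append(ks_normality(s)[1] if s.size >= 5 else math.nan)
        except ValueError:
            norm_p.append(math.nan)
    tt = students_t(samples[0], samples[1])
    comparison = ComparisonResult(
        group_labels=(ordered[0], ordered[1]),
        n=(samples[0].size, samples[1].size),
        means=(float(samples[0].mean()), float(samples[1].mean())),
        sems=(
            float(sps.sem(samples[0])),
            float(sps.sem(samples[1])),
        ),
        percent_reduction=percent_reduction(samples[0], samples[1]),
        t_statistic=tt.t,
        degrees_of_freedom=tt.df,
        p_value=tt.p,
        stars=significance_annotation(tt.p),
        normality_p=(norm_p[0], norm_p[1]),
    )
    estimation = bootstrap_mean_difference(
        samples[0], samples[1], n_resamples=n_resamples, seed=seed
    )
    if len(ordered) > 2:
        multi = dunns_multiple_comparison(samples, labels=ordered, control=0)
        return comparison, estimation, multi
    return comparison, estimation
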