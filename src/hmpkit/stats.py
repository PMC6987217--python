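"""Statistical battery: exact one-tailed rank-sum, paired t, simple OLS,
and the standardized mean difference with unweighted variance pooling.

The rank-sum test is exact (full null distribution of the rank sum via a
subset-sum counting recursion) whenever the pooled sample is tie-free and
has at most ``EXACT_CUTOFF`` observations; otherwise midranks with the
tie-corrected normal approximation and continuity correction are used.

The standardized mean difference is

    d = (mean_j - mean_i) / sqrt((var_j + var_i) / 2)

i.e. the *unweighted* average of the two sample variances — deliberately
not the n-weighted pooled estimator; |d| >= 0.2 / 0.5 / 0.8 classify as
small / medium / large.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cartilage import REGIONS
from .config import AnalysisConfig
from .errors import ConstantInputError, SubjectMismatchError, ZeroVarianceError
from .hmp import SubjectDeviationSummary, split_groups

#: Largest pooled sample size for which the exact null distribution is used.
EXACT_CUTOFF = 20


@dataclass(frozen=True)
class RankSumResult:
    rank_sum_W: float
    p_one_tailed: float
    method: str  # "exact" | "normal_approx"
    n_x: int
    n_y: int


@dataclass(frozen=True)
class PairedTResult:
    t_statistic: float
    df: int
    p_value: float
    tail: str  # "one" | "two"


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n: int
    slope_stderr: float

    def slope_confidence_interval(self, level: float = 0.95) -> Tuple[float, float]:
        half = sps.t.ppf(0.5 + level / 2.0, self.n - 2) * self.slope_stderr
        return self.slope - half, self.slope + half


@dataclass(frozen=True)
class EffectSize:
    d: float
    mean_j: float
    mean_i: float
    var_j: float
    var_i: float
    magnitude: str


@dataclass
class StudyResult:
    """Per-region test rows plus the group split that produced them."""

    high_group: List[str]
    low_group: List[str]
    alpha: float
    rows: List[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_json_dict(self) -> dict:
        return {
            "high_group": self.high_group,
            "low_group": self.low_group,
            "alpha": self.alpha,
            "tests": self.rows,
        }


def _ranksum_null_counts(n_total: int, n_x: int) -> np.ndarray:
    """counts[s] = number of n_x-subsets of ranks {1..n_total} with sum s."""
    max_sum = n_total * (n_total + 1) // 2
    counts = np.zeros((n_x + 1, max_sum + 1), dtype=np.int64)
    counts[0, 0] = 1
    for r in range(1, n_total + 1):
        upper = min(r, n_x)
        for k in range(upper, 0, -1):
            counts[k, r:] += counts[k - 1, : max_sum + 1 - r]
    return counts[n_x]


def wilcoxon_rank_sum_one_tailed(
    x: Sequence[float], y: Sequence[float], alternative: str = "x_greater"
) -> RankSumResult:
    """One-tailed two-sample rank-sum test.

    ``alternative="x_greater"`` tests whether x tends to exceed y. Exact
    enumeration of the null rank-sum distribution when the pooled sample is
    tie-free with n <= 20; midranks + tie-corrected normal approximation
    with continuity correction otherwise.
    """
    if alternative not in ("x_greater", "x_less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative == "x_less":
        x, y = y, x
    n_x, n_y = x.size, y.size
    n = n_x + n_y
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks under ties
    w = float(ranks[:n_x].sum())
    has_ties = np.unique(pooled).size < n

    if not has_ties and n <= EXACT_CUTOFF:
        counts = _ranksum_null_counts(n, n_x)
        total = math.comb(n, n_x)
        p = float(counts[int(round(w)):].sum()) / total
        method = "exact"
    else:
        mu = n_x * (n + 1) / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = n_x * n_y / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 0.5  # all observations identical: W at its null expectation
        else:
            z = (w - mu - 0.5) / math.sqrt(var)
            p = float(sps.norm.sf(z))
        method = "normal_approx"
    if alternative == "x_less":
        n_x, n_y = n_y, n_x
    return RankSumResult(
        rank_sum_W=w, p_one_tailed=min(p, 1.0), method=method, n_x=n_x, n_y=n_y
    )


def paired_t(diffs: Sequence[float], tail: str = "two") -> PairedTResult:
    """One-sample t on paired differences against a zero mean."""
    if tail not in ("one", "two"):
        raise ValueError(f"unknown tail {tail!r}")
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 paired differences")
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise ZeroVarianceError("paired differences have zero variance")
    t = float(d.mean() / (sd / math.sqrt(d.size)))
    df = d.size - 1
    if tail == "two":
        p = 2.0 * float(sps.t.sf(abs(t), df))
    else:
        p = float(sps.t.sf(t, df))
    return PairedTResult(t_statistic=t, df=df, p_value=p, tail=tail)


def linear_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x with the slope's two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]):
        raise ConstantInputError("predictor x is constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        fit = sps.linregress(x, y)
    r2 = float(fit.rvalue**2)
    p = float(fit.pvalue)
    if np.all(y == y[0]):  # SST = 0: flat response, no explainable variance
        r2, p = 0.0, 1.0
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=min(max(r2, 0.0), 1.0),
        p_slope=p,
        n=int(x.size),
        slope_stderr=float(fit.stderr),
    )


def _classify(d: float) -> str:
    a = abs(d)
    if a >= 0.8:
        return "large"
    if a >= 0.5:
        return "medium"
    if a >= 0.2:
        return "small"
    return "negligible"


def cohens_d(mean_j: float, var_j: float, mean_i: float, var_i: float) -> EffectSize:
    """Standardized mean difference with unweighted variance average."""
    if var_j + var_i <= 0:
        raise ZeroVarianceError("both variances are zero")
    d = (mean_j - mean_i) / math.sqrt((var_j + var_i) / 2.0)
    return EffectSize(
        d=float(d),
        mean_j=float(mean_j),
        mean_i=float(mean_i),
        var_j=float(var_j),
        var_i=float(var_i),
        magnitude=_classify(d),
    )


def cohens_d_from_samples(xj: Sequence[float], xi: Sequence[float]) -> EffectSize:
    xj = np.asarray(xj, dtype=float)
    xi = np.asarray(xi, dtype=float)
    return cohens_d(
        float(xj.mean()), float(xj.var(ddof=1)), float(xi.mean()), float(xi.var(ddof=1))
    )


def _holm(pvals: List[Optional[float]]) -> List[Optional[float]]:
    """Holm step-down adjustment; None entries pass through."""
    idx = [i for i, p in enumerate(pvals) if p is not None]
    m = len(idx)
    order = sorted(idx, key=lambda i: pvals[i])
    adjusted: List[Optional[float]] = [None] * len(pvals)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adjusted[i] = min(running, 1.0)
    return adjusted


def run_study_analysis(
    summaries: Sequence[SubjectDeviationSummary],
    reductions: pd.DataFrame,
    config: Optional[AnalysisConfig] = None,
) -> StudyResult:
    """Full per-region statistical battery.

    For each of the seven regions: (a) one-tailed rank-sum that the high
    deviation half shows larger cross-shoe-averaged reductions than the low
    half, with the standardized group difference; (b) paired t comparing
    each subject's maximum- vs minimum-deviation shoe, with the footwear
    effect size; (c) simple regression of the subject-averaged reduction on
    overall deviation. Significance at ``config.alpha``; no multiplicity
    correction unless ``config.holm_correction``.
    """
    config = config or AnalysisConfig()
    dev_subjects = {s.subject_id for s in summaries}
    red_subjects = set(reductions["subject"].astype(str))
    missing = sorted(dev_subjects.symmetric_difference(red_subjects))
    if missing:
        raise SubjectMismatchError(
            "deviation and reduction tables disagree on subjects: "
            + ", ".join(missing),
            missing=missing,
        )

    high, low = split_groups(list(summaries))
    high_ids = [s.subject_id for s in high]
    low_ids = [s.subject_id for s in low]
    by_id = {s.subject_id: s for s in summaries}
    overall = {s.subject_id: s.overall_deg for s in summaries}

    # subject x region cross-shoe average reductions
    avg = (
        reductions.groupby(["subject", "region"], sort=False)["pct_reduction"]
        .mean()
        .unstack("region")
    )
    per_cond = reductions.set_index(["subject", "condition", "region"])["pct_reduction"]

    result = StudyResult(high_group=high_ids, low_group=low_ids, alpha=config.alpha)
    for region in REGIONS:
        xh = avg.loc[high_ids, region].to_numpy(dtype=float)
        xl = avg.loc[low_ids, region].to_numpy(dtype=float)

        rs = wilcoxon_rank_sum_one_tailed(xh, xl, alternative="x_greater")
        try:
            d_group = cohens_d_from_samples(xh, xl)
            d_group_val, d_group_mag = d_group.d, d_group.magnitude
        except ZeroVarianceError:
            d_group_val, d_group_mag = None, None
        result.rows.append(
            {
                "region": region,
                "test": "ranksum_group",
                "statistic": rs.rank_sum_W,
                "p_value": rs.p_one_tailed,
                "method": rs.method,
                "d": d_group_val,
                "magnitude": d_group_mag,
                "n": rs.n_x + rs.n_y,
                "note": None,
            }
        )

        max_vals, min_vals = [], []
        for sid in avg.index:
            summ = by_id[str(sid)]
            max_vals.append(float(per_cond.loc[(sid, summ.max_shoe, region)]))
            min_vals.append(float(per_cond.loc[(sid, summ.min_shoe, region)]))
        diffs = np.asarray(max_vals) - np.asarray(min_vals)
        try:
            pt = paired_t(diffs, tail="two")
            stat, p, note = pt.t_statistic, pt.p_value, None
        except ZeroVarianceError:
            stat, p, note = None, None, "zero variance; paired t not computable"
        try:
            d_shoe = cohens_d_from_samples(max_vals, min_vals)
            d_shoe_val, d_shoe_mag = d_shoe.d, d_shoe.magnitude
        except ZeroVarianceError:
            d_shoe_val, d_shoe_mag = None, None
        result.rows.append(
            {
                "region": region,
                "test": "paired_t_footwear",
                "statistic": stat,
                "p_value": p,
                "method": "t_two_tailed",
                "d": d_shoe_val,
                "magnitude": d_shoe_mag,
                "n": int(diffs.size),
                "note": note,
            }
        )

        xs = [overall[str(sid)] for sid in avg.index]
        ys = avg[region].to_numpy(dtype=float)
        try:
            reg = linear_regression(xs, ys)
            result.rows.append(
                {
                    "region": region,
                    "test": "regression",
                    "statistic": reg.slope,
                    "p_value": reg.p_slope,
                    "method": "ols",
                    "r_squared": reg.r_squared,
                    "intercept": reg.intercept,
                    "d": None,
                    "magnitude": None,
                    "n": reg.n,
                    "note": None,
                }
            )
        except ConstantInputError:
            result.rows.append(
                {
                    "region": region,
                    "test": "regression",
                    "statistic": None,
                    "p_value": None,
                    "method": "ols",
                    "d": None,
                    "magnitude": None,
                    "n": len(xs),
                    "note": "constant predictor; regression not computable",
                }
            )

    if config.holm_correction:
        for family in ("ranksum_group", "paired_t_footwear", "regression"):
            rows = [r for r in result.rows if r["test"] == family]
            adj = _holm([r["p_value"] for r in rows])
            for r, p in zip(rows, adj):
                r["p_holm"] = p
    for r in result.rows:
        p_eff = r.get("p_holm", r["p_value"]) if config.holm_correction else r["p_value"]
        r["significant"] = bool(p_eff is not None and p_eff < config.alpha)
    return result
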