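"""Method-comparison statistics for calibrating the automated quantifier.

The automated method (AM) is calibrated against the manual method (MM) on
a set of eyes measured by both, and validated on a second set where the
manual measurement is repeated five times.  The statistical toolkit:

* Deming regression — an errors-in-variables line fit that allows
  measurement error on both axes, appropriate when neither method is a
  gold standard.  With error-variance ratio λ = 1 it minimises
  perpendicular distances (the default here, matching common method-
  comparison practice).
* Bland-Altman analysis — per-pair differences (AM − MM) against per-pair
  averages; limits of agreement are mean ± 1.96 SD of the differences.
* Compensation — an ordinary least-squares fit of difference on average
  over the calibration set, used to correct proportional + constant bias
  in subsequent AM values.
* Replicate confidence intervals and coverage — a t-based 95% CI from the
  repeated manual measurements of each eye, and the fraction of eyes
  whose compensated AM value falls inside its CI.
* Mann-Whitney rank-sum comparison of group distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AgreementError",
    "DemingFit",
    "BlandAltman",
    "CompensationModel",
    "deming_fit",
    "bland_altman",
    "fit_compensation",
    "apply_compensation",
    "replicate_ci",
    "coverage",
    "rank_sum_compare",
]


class AgreementError(ValueError):
    """Invalid input to an agreement-statistics routine."""


@dataclass
class DemingFit:
    """Errors-in-variables line fit ``y = slope * x + intercept``.

    ``r_squared`` is the squared Pearson correlation of x and y (Deming
    regression has no canonical R²; the squared correlation is the single
    scalar conventionally reported alongside it).  ``slope_se`` and
    ``intercept_se`` are leave-one-out jackknife standard errors when
    requested, else None.
    """

    slope: float
    intercept: float
    r_squared: float
    lam: float
    n: int
    slope_se: float | None = None
    intercept_se: float | None = None

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "r_squared": self.r_squared, "lambda": self.lam, "n": self.n,
                "slope_se": self.slope_se, "intercept_se": self.intercept_se}


@dataclass
class BlandAltman:
    """Difference-vs-average agreement summary (differences are y − x)."""

    mean_diff: float
    sd_diff: float
    loa_lo: float
    loa_hi: float
    diff_vs_avg_slope: float
    diff_vs_avg_intercept: float
    n: int

    def to_dict(self) -> dict:
        return {"mean_diff": self.mean_diff, "sd_diff": self.sd_diff,
                "loa_lo": self.loa_lo, "loa_hi": self.loa_hi,
                "diff_vs_avg_slope": self.diff_vs_avg_slope,
                "diff_vs_avg_intercept": self.diff_vs_avg_intercept, "n": self.n}


@dataclass
class CompensationModel:
    """Bias model ``difference ≈ a + b * average`` fitted on calibration data."""

    a: float
    b: float

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b}


def _as_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise AgreementError("x and y must have the same length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise AgreementError("x and y must be finite with no missing values")
    return x, y


def _deming_slope_intercept(x: np.ndarray, y: np.ndarray,
                            lam: float) -> tuple[float, float]:
    sxx = np.var(x, ddof=1)
    syy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    if sxy == 0:
        raise AgreementError("covariance of x and y is zero; line orientation undefined")
    d = syy - lam * sxx
    slope = (d + np.sqrt(d * d + 4.0 * lam * sxy * sxy)) / (2.0 * sxy)
    intercept = y.mean() - slope * x.mean()
    return float(slope), float(intercept)


def deming_fit(x, y, lam: float = 1.0, ci: bool = False) -> DemingFit:
    """Fit a Deming regression of y on x.

    ``lam`` is the ratio of error variances; the closed-form slope is

        [s_yy − λ s_xx + sqrt((s_yy − λ s_xx)² + 4 λ s_xy²)] / (2 s_xy)

    and the line passes through the centroid.  As λ → ∞ the fit tends to
    ordinary least squares of y on x; at λ = 1 it is the orthogonal fit.
    ``ci=True`` adds jackknife (leave-one-out) standard errors for slope
    and intercept.
    """
    x, y = _as_xy(x, y)
    n = x.size
    if n < 3:
        raise AgreementError(f"Deming regression needs n >= 3, got {n}")
    if np.var(x, ddof=1) == 0:
        raise AgreementError("x has zero variance")
    if lam <= 0:
        raise AgreementError("lambda must be positive")
    slope, intercept = _deming_slope_intercept(x, y, lam)
    r = stats.pearsonr(x, y).statistic
    slope_se = intercept_se = None
    if ci:
        slopes = np.empty(n)
        intercepts = np.empty(n)
        keep = np.ones(n, bool)
        for i in range(n):
            keep[i] = False
            slopes[i], intercepts[i] = _deming_slope_intercept(x[keep], y[keep], lam)
            keep[i] = True
        slope_se = float(np.sqrt((n - 1) / n * np.sum((slopes - slopes.mean()) ** 2)))
        intercept_se = float(np.sqrt((n - 1) / n
                                     * np.sum((intercepts - intercepts.mean()) ** 2)))
    return DemingFit(slope=slope, intercept=intercept, r_squared=float(r * r),
                     lam=float(lam), n=int(n),
                     slope_se=slope_se, intercept_se=intercept_se)


def bland_altman(x, y) -> BlandAltman:
    """Bland-Altman agreement of method y against method x.

    Differences are ``d_i = y_i − x_i``; the SD uses the n−1 denominator
    and the limits of agreement are ``mean ± 1.96 SD``.  An OLS regression
    of difference on average quantifies proportional bias (slope 0 when
    disagreement does not grow with the measured level).
    """
    x, y = _as_xy(x, y)
    if x.size < 2:
        raise AgreementError("Bland-Altman needs n >= 2")
    d = y - x
    avg = (x + y) / 2.0
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.var(avg) > 0:
        fit = stats.linregress(avg, d)
        b, a = float(fit.slope), float(fit.intercept)
    else:
        b, a = 0.0, mean
    return BlandAltman(mean_diff=mean, sd_diff=sd,
                       loa_lo=mean - 1.96 * sd, loa_hi=mean + 1.96 * sd,
                       diff_vs_avg_slope=b, diff_vs_avg_intercept=a, n=int(x.size))


def fit_compensation(x, y) -> CompensationModel:
    """OLS of difference (y − x) on average, on the calibration set."""
    x, y = _as_xy(x, y)
    if x.size < 3:
        raise AgreementError(f"compensation fit needs n >= 3, got {x.size}")
    avg = (x + y) / 2.0
    if np.var(avg) == 0:
        raise AgreementError("averages are constant; compensation undefined")
    fit = stats.linregress(avg, y - x)
    return CompensationModel(a=float(fit.intercept), b=float(fit.slope))


def apply_compensation(model: CompensationModel, am, mm=None):
    """Correct AM value(s) with the fitted bias model.

    When the paired MM value is supplied the predicted bias is evaluated
    at the pair average, ``am − (a + b·(am + mm)/2)`` — the exact inverse
    of the fitted relation, which drives a refitted difference-vs-average
    regression on the same data to (0, 0).  For a lone AM value the AM
    itself stands in for the average: ``am − (a + b·am)``; with b = 0 both
    forms reduce to subtracting the mean bias.
    """
    am = np.asarray(am, dtype=float)
    if mm is None:
        out = am - (model.a + model.b * am)
    else:
        mm = np.asarray(mm, dtype=float)
        out = am - (model.a + model.b * (am + mm) / 2.0)
    return float(out) if out.ndim == 0 else out


def replicate_ci(replicates, conf: float = 0.95) -> tuple[float, float, float]:
    """t-based confidence interval from repeated measurements of one unit.

    With k replicates the interval is mean ± t(1−α/2, k−1) · s/√k; the
    design this emulates uses k = 5 (df = 4).
    """
    r = np.asarray(replicates, dtype=float).ravel()
    k = r.size
    if k < 2:
        raise AgreementError(f"need at least 2 replicates, got {k}")
    mean = float(r.mean())
    half = float(stats.t.ppf(0.5 + conf / 2.0, k - 1) * r.std(ddof=1) / np.sqrt(k))
    return mean, mean - half, mean + half


def coverage(values: Mapping[str, float],
             cis: Mapping[str, tuple[float, float]]) -> tuple[int, float]:
    """Count units whose value lies inside its closed interval.

    ``values`` maps unit id to (compensated) AM value; ``cis`` maps the
    same ids to (lo, hi) replicate intervals.  The two id sets must match
    exactly.  Returns (n_inside, fraction).
    """
    v_ids, c_ids = set(values), set(cis)
    if not v_ids or v_ids != c_ids:
        raise AgreementError(
            f"unit ids must match: {sorted(v_ids ^ c_ids)[:5]} differ"
            if v_ids else "no units supplied")
    n_inside = sum(1 for u in values if cis[u][0] <= values[u] <= cis[u][1])
    return n_inside, n_inside / len(values)


def rank_sum_compare(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney comparison of two groups.

    Uses exact permutation enumeration (handling midranks for ties) when
    either group has fewer than 8 observations, and the tie-corrected
    normal approximation otherwise.  Returns (U, p).
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise AgreementError("both groups must be non-empty")
    if min(a.size, b.size) < 8:
        method = stats.PermutationMethod(n_resamples=200_000, rng=0)
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
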