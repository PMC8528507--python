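"""Test-retest reliability statistics for subjects-by-repeats matrices.

The unit of analysis is a complete subjects x repeats grid of one TMS
parameter.  The battery mirrors standard agreement methodology:

* repeatability — within-subject SD ``sigma_w`` from the one-way
  subjects ANOVA and the coefficient of repeatability
  ``CR = 1.96 * sqrt(2) * sigma_w`` (the bound that the difference between
  two future replicate measurements will not exceed on 95% of occasions);
  on log10-scaled data CR back-transforms to a fold-change ratio;
* reliability — ICC(2,1), the two-way random-effects, single-rating,
  absolute-agreement intraclass correlation, with F-based confidence
  bounds and the conventional poor/moderate/good/excellent bands;
* reproducibility — one-within-factor repeated-measures ANOVA with
  Mauchly's sphericity test, Greenhouse-Geisser correction and
  Bonferroni-corrected pairwise post hocs; Bland-Altman bias and limits
  of agreement (back-transformed to ratios on the log scale); one-sample
  and paired t tests; and the inter-method regression of the
  threshold-tracked readout on the log amplitude-ratio readout.

All mean squares are computed definitionally so each statistic can be
verified against independent oracles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MeasurementMatrix",
    "ReliabilityReport",
    "within_subject_sd",
    "coefficient_of_repeatability",
    "icc_2_1",
    "classify_icc",
    "rm_anova",
    "bonferroni_posthoc",
    "bland_altman",
    "one_sample_condition_test",
    "paired_t",
    "method_regression",
]


@dataclass
class MeasurementMatrix:
    """A subjects x repeats grid of one parameter.

    Rows with any missing value are dropped (listwise deletion) on
    construction; reliability statistics require at least two complete
    subjects and two repeats.  ``scale`` records whether the values are
    raw ("linear") or log10-transformed ("log10"), which controls
    back-transformation of CR and Bland-Altman outputs.
    """

    values: np.ndarray
    parameter_name: str = ""
    scale: str = "linear"
    units: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise ValueError("values must be a 2-D subjects x repeats array")
        complete = ~np.isnan(arr).any(axis=1)
        self.n_dropped = int((~complete).sum())
        self.values = arr[complete]
        if self.scale not in ("linear", "log10"):
            raise ValueError("scale must be 'linear' or 'log10'")

    @classmethod
    def from_wide_csv(cls, path, parameter_name: str = "", scale: str = "linear",
                      units: str = "") -> "MeasurementMatrix":
        """Read a wide-format CSV: one row per subject, one column per repeat."""
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), parameter_name, scale, units)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_repeats(self) -> int:
        return self.values.shape[1]

    def _require(self, min_subjects: int = 2, min_repeats: int = 2) -> None:
        if self.n_subjects < min_subjects or self.n_repeats < min_repeats:
            raise ValueError(
                f"need at least {min_subjects} subjects and {min_repeats} repeats; "
                f"got {self.n_subjects} x {self.n_repeats}"
            )


class RmAnovaResult(NamedTuple):
    F: float
    df1: float
    df2: float
    p: float
    epsilon: float
    mauchly_p: float


@dataclass
class ReliabilityReport:
    """Bundle of the reliability battery for one MeasurementMatrix."""

    parameter_name: str
    cr: float
    cr_ci: tuple[float, float]
    cr_fold: float | None  # back-transformed 10**cr on log10 scale
    icc: float
    icc_ci: tuple[float, float]
    icc_band: str
    anova: RmAnovaResult | None


def _mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way (subjects x repeats) mean squares: (MSR, MSC, MSE)."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_tot = float(((x - grand) ** 2).sum())
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def within_subject_sd(m: MeasurementMatrix) -> float:
    """sigma_w: root mean square within subjects (one-way subjects ANOVA).

    For exactly two repeats this reduces to ``sqrt(sum(d^2) / (2n))`` over
    the paired differences d.
    """
    m._require(min_subjects=1)
    x = m.values
    n, k = x.shape
    ss_within = float(((x - x.mean(axis=1, keepdims=True)) ** 2).sum())
    return math.sqrt(ss_within / (n * (k - 1)))


def coefficient_of_repeatability(
    m: MeasurementMatrix, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """CR = 1.96 * sqrt(2) * sigma_w with a chi-square 95% CI.

    The CI treats ``n(k-1) * sigma_w^2 / sigma^2`` as chi-square with
    n(k-1) degrees of freedom.  On a log10 scale the caller should report
    ``10**cr`` as the fold-change bound between two future replicates.
    """
    sw = within_subject_sd(m)
    df = m.n_subjects * (m.n_repeats - 1)
    lo = sw * math.sqrt(df / stats.chi2.ppf(1 - alpha / 2, df))
    hi = sw * math.sqrt(df / stats.chi2.ppf(alpha / 2, df))
    c = 1.96 * math.sqrt(2.0)
    return c * sw, (c * lo, c * hi)


def icc_2_1(
    m: MeasurementMatrix, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, single rating, absolute agreement.

    ``ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))`` from the
    two-way mean squares; the CI uses the standard F-distribution bounds
    with a Satterthwaite approximation for the denominator df.  Zero total
    variance yields (nan, (nan, nan)).
    """
    m._require()
    x = m.values
    n, k = x.shape
    if np.ptp(x) == 0:
        return math.nan, (math.nan, math.nan)
    msr, msc, mse = _mean_squares(x)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return math.nan, (math.nan, math.nan)
    icc = (msr - mse) / denom
    if mse <= 0:
        # Perfect agreement: degenerate F bounds.
        return icc, (icc, icc)
    fj = msc / mse
    vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = vn / vd
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return float(icc), (float(lower), float(upper))


def classify_icc(icc: float) -> str:
    """Qualitative reliability band: poor/moderate/good/excellent.

    Poor below 0.50, moderate 0.50-0.749, good 0.75-0.90 (upper bound
    inclusive), excellent above 0.90.
    """
    if math.isnan(icc):
        return "undefined"
    if icc > 1 + 1e-9:
        raise ValueError("ICC cannot exceed 1")
    icc = min(icc, 1.0)
    if icc < 0.50:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.90:
        return "good"
    return "excellent"


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k matrix with orthonormal rows, each orthogonal to ones."""
    h = np.eye(k) - np.full((k, k), 1.0 / k)
    # QR of the centering projector spans the contrast space.
    q, _ = np.linalg.qr(h)
    return q[:, : k - 1].T


def rm_anova(m: MeasurementMatrix, gg_threshold: float = 0.05) -> RmAnovaResult:
    """One-within-factor repeated-measures ANOVA on the repeats.

    Returns the omnibus F with its (possibly corrected) degrees of
    freedom, Mauchly's sphericity p value and the Greenhouse-Geisser
    epsilon; the correction is applied when Mauchly's p falls below
    ``gg_threshold``.  A two-level factor is trivially spherical
    (W = 1, epsilon = 1).
    """
    m._require()
    x = m.values
    n, k = x.shape
    msr, msc, mse = _mean_squares(x)
    df1 = float(k - 1)
    df2 = float((n - 1) * (k - 1))
    F = msc / mse if mse > 0 else math.inf

    C = _orthonormal_contrasts(k)
    S = np.cov(x, rowvar=False, ddof=1)
    Sc = C @ S @ C.T
    tr = float(np.trace(Sc))
    eps_lower = 1.0 / (k - 1)
    if k == 2:
        epsilon, mauchly_p = 1.0, 1.0
    else:
        denom = (k - 1) * float(np.trace(Sc @ Sc))
        epsilon = tr**2 / denom if denom > 0 else eps_lower
        det = float(np.linalg.det(Sc))
        if det <= 0 or tr <= 0:
            # Singular covariance: sphericity maximally violated.
            warnings.warn("singular repeated-measures covariance; epsilon at lower bound")
            epsilon, mauchly_p = eps_lower, 0.0
        else:
            W = det / (tr / (k - 1)) ** (k - 1)
            p_ = k - 1
            f_corr = 1.0 - (2 * p_**2 + p_ + 2) / (6.0 * p_ * (n - 1))
            chi2_stat = -(n - 1) * f_corr * math.log(W)
            df_w = p_ * (p_ + 1) / 2.0 - 1.0
            mauchly_p = float(stats.chi2.sf(max(chi2_stat, 0.0), df_w))
        epsilon = float(np.clip(epsilon, eps_lower, 1.0))

    if mauchly_p < gg_threshold:
        df1 *= epsilon
        df2 *= epsilon
    p = float(stats.f.sf(F, df1, df2)) if math.isfinite(F) else 0.0
    return RmAnovaResult(float(F), df1, df2, p, float(epsilon), float(mauchly_p))


def bonferroni_posthoc(m: MeasurementMatrix) -> pd.DataFrame:
    """Pairwise paired t tests over repeats, Bonferroni-corrected."""
    m._require()
    x = m.values
    k = x.shape[1]
    ncomp = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            t, p = stats.ttest_rel(x[:, i], x[:, j])
            rows.append(
                {"rep_a": i + 1, "rep_b": j + 1, "t": float(t),
                 "p_uncorrected": float(p), "p_bonferroni": min(1.0, float(p) * ncomp)}
            )
    return pd.DataFrame(rows)


def bland_altman(
    a: np.ndarray, b: np.ndarray, scale: str = "linear"
) -> tuple[float, float, float]:
    """Bland-Altman bias and 95% limits of agreement for paired repeats.

    ``bias = mean(a - b)``, limits ``bias +/- 1.96 * SD(a - b)``.  On the
    log10 scale all three are back-transformed to ratios (geometric-mean
    ratio and fold limits).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    if scale == "log10":
        return 10.0**bias, 10.0**lo, 10.0**hi
    return bias, lo, hi


def one_sample_condition_test(
    values: np.ndarray, null_value: float
) -> tuple[float, int, float]:
    """Two-sided one-sample t test against a control condition value."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    if values.std(ddof=1) == 0:
        # degenerate sample: on the null exactly, or infinitely far from it
        if values[0] == null_value:
            return 0.0, values.size - 1, 1.0
        return math.copysign(math.inf, values[0] - null_value), values.size - 1, 0.0
    res = stats.ttest_1samp(values, null_value)
    return float(res.statistic), values.size - 1, float(res.pvalue)


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Two-sided paired t test (e.g. observer 1 vs observer 2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need paired arrays with at least 2 pairs")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), a.size - 1, float(res.pvalue)


class MethodRegression(NamedTuple):
    slope: float
    intercept: float
    r: float
    r_ci95: tuple[float, float]
    p: float


def method_regression(
    t_sici_means: np.ndarray, a_sici_means: np.ndarray
) -> MethodRegression:
    """OLS of per-subject T-SICI means on log10 per-subject A-SICI means.

    Returns the regression line, Pearson r with its Fisher-z 95% CI, and
    the correlation p value.  ``a_sici_means`` are raw percent-of-control
    values; the predictor is their log10.
    """
    y = np.asarray(t_sici_means, dtype=float)
    a = np.asarray(a_sici_means, dtype=float)
    if y.size != a.size or y.size < 3:
        raise ValueError("need at least 3 paired subject means")
    if np.any(a <= 0):
        raise ValueError("A-SICI values must be positive for the log transform")
    x = np.log10(a)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    res = stats.linregress(x, y)
    r = float(res.rvalue)
    if y.size > 3 and abs(r) < 1:
        z = math.atanh(r)
        se = 1.0 / math.sqrt(y.size - 3)
        ci = (math.tanh(z - 1.96 * se), math.tanh(z + 1.96 * se))
    else:
        ci = (math.nan, math.nan)
    return MethodRegression(
        float(res.slope), float(res.intercept), r, ci, float(res.pvalue)
    )


def reliability_report(m: MeasurementMatrix, run_anova: bool = True) -> ReliabilityReport:
    """Convenience wrapper computing the full battery for one matrix."""
    cr, cr_ci = coefficient_of_repeatability(m)
    icc, icc_ci = icc_2_1(m)
    return ReliabilityReport(
        parameter_name=m.parameter_name,
        cr=cr,
        cr_ci=cr_ci,
        cr_fold=10.0**cr if m.scale == "log10" else None,
        icc=icc,
        icc_ci=icc_ci,
        icc_band=classify_icc(icc),
        anova=rm_anova(m) if run_anova and m.n_repeats >= 2 else None,
    )
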