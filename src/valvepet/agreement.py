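"""Scan-rescan and observer agreement statistics, and the sample-size
framework for trials using valvular 18F-fluoride uptake as an end point.

Implements Bland-Altman limits of agreement, percentage error (twice the
SD of the paired differences over the overall mean), Cohen's kappa with
an asymptotic 95% CI and the conventional interpretation bands, the
two-way absolute-agreement single-measure ICC, and per-group sample
sizes for a two-sided two-sample t-test evaluated with the noncentral-t
distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats import inter_rater

LOA_MULTIPLIER = 1.96
# half-width acceptability criterion for TBR_MDSmean scan-rescan agreement
ACCEPTABLE_LOA_HALF_WIDTH = 0.2

KAPPA_BANDS = (
    (0.20, "poor"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "good"),
    (1.00, "very good"),
)


class AgreementError(ValueError):
    pass


@dataclass
class PairedMeasurements:
    """Aligned repeat measurements of one metric on the same subjects."""

    m1: np.ndarray
    m2: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        self.m1 = np.asarray(self.m1, dtype=float)
        self.m2 = np.asarray(self.m2, dtype=float)
        if self.m1.shape != self.m2.shape or self.m1.ndim != 1:
            raise AgreementError("measurement lists must be 1-D and equal length")
        if self.m1.size < 2:
            raise AgreementError("need at least 2 pairs")
        if not (np.all(np.isfinite(self.m1)) and np.all(np.isfinite(self.m2))):
            raise AgreementError("measurements must be finite")

    @property
    def differences(self) -> np.ndarray:
        return self.m1 - self.m2


@dataclass
class AgreementReport:
    """Bland-Altman summary for one metric's paired measurements."""

    metric: str
    n: int
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    loa_half_width: float
    percentage_error: float | None
    acceptable: bool

    def to_dict(self) -> dict:
        return dict(metric=self.metric, n=self.n, bias=self.bias,
                    sd_diff=self.sd_diff, loa_lower=self.loa_lower,
                    loa_upper=self.loa_upper, loa_half_width=self.loa_half_width,
                    percentage_error=self.percentage_error,
                    acceptable=self.acceptable)

    def summary(self) -> str:
        pe = ("n/a" if self.percentage_error is None
              else f"{self.percentage_error:.1f}%")
        return (f"{self.metric or 'metric'} (n={self.n}): "
                f"bias {self.bias:+.3f}, 95% LoA [{self.loa_lower:.3f}, "
                f"{self.loa_upper:.3f}] (half-width {self.loa_half_width:.3f}), "
                f"percentage error {pe}")


@dataclass
class KappaResult:
    kappa: float
    ci_lower: float
    ci_upper: float
    band: str

    def to_dict(self) -> dict:
        return dict(kappa=self.kappa, ci_lower=self.ci_lower,
                    ci_upper=self.ci_upper, band=self.band)


def bland_altman(pairs: PairedMeasurements) -> AgreementReport:
    """Bland-Altman analysis: bias = mean(m1 - m2), 95% limits of
    agreement = bias +/- 1.96 x sample SD of the differences.  The
    acceptability flag records whether the LoA half-width is within the
    0.2 criterion used for TBR_MDSmean."""
    d = pairs.differences
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half = LOA_MULTIPLIER * sd
    overall = float(np.concatenate([pairs.m1, pairs.m2]).mean())
    pe = percentage_error(pairs) if overall > 0 else None
    return AgreementReport(
        metric=pairs.metric, n=int(d.size), bias=bias, sd_diff=sd,
        loa_lower=bias - half, loa_upper=bias + half, loa_half_width=half,
        percentage_error=pe,
        acceptable=half <= ACCEPTABLE_LOA_HALF_WIDTH + 1e-9)


def percentage_error(pairs: PairedMeasurements) -> float:
    """Percentage error: 100 x 2 x SD(differences) / mean of all 2n
    measurements.  Captures variability, not bias: a constant offset
    between the two lists gives 0%."""
    overall = float(np.concatenate([pairs.m1, pairs.m2]).mean())
    if overall <= 0:
        raise AgreementError("overall mean must be positive for percentage error")
    return 100.0 * 2.0 * float(pairs.differences.std(ddof=1)) / overall


def kappa_band(kappa: float) -> str:
    """Interpretation band for kappa: poor <= 0.20 < fair <= 0.40 <
    moderate <= 0.60 < good <= 0.80 < very good <= 1."""
    if not (-1.0 - 1e-12 <= kappa <= 1.0 + 1e-12):
        raise AgreementError(f"kappa {kappa} outside [-1, 1]")
    for upper, label in KAPPA_BANDS:
        if kappa <= upper + 1e-12:
            return label
    return KAPPA_BANDS[-1][1]


def cohens_kappa(table) -> KappaResult:
    """Cohen's kappa for a square contingency table of paired categorical
    calls, with an asymptotic-SE 95% CI and its interpretation band."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise AgreementError("contingency table must be square")
    if table.sum() < 1:
        raise AgreementError("empty contingency table")
    n = table.sum()
    p = table / n
    pe = float(p.sum(axis=0) @ p.sum(axis=1))
    if abs(1.0 - pe) < 1e-12:
        raise AgreementError("degenerate margins: chance agreement is 1, kappa undefined")
    res = inter_rater.cohens_kappa(table, return_results=True)
    k = float(res.kappa)
    se = float(np.sqrt(res.var_kappa))
    return KappaResult(k, k - 1.96 * se, k + 1.96 * se, kappa_band(max(-1.0, min(1.0, k))))


def icc(ratings) -> float:
    """Two-way, absolute-agreement, single-measure intraclass correlation
    (ICC(A,1)) for a subjects x raters table, from the standard
    mean-squares decomposition:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR/MSC/MSE the subject, rater and residual mean squares."""
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[0] < 2 or ratings.shape[1] < 2:
        raise AgreementError("need >= 2 subjects and >= 2 raters")
    if np.ptp(ratings) == 0:
        raise AgreementError("constant ratings: ICC undefined")
    n, k = ratings.shape
    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((ratings - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise AgreementError("degenerate ratings: ICC undefined")
    return float((msr - mse) / denom)


# ---------------------------------------------------------------------------
# sample size


def power_two_sample_t(n_per_group: int, delta: float, sd: float,
                       alpha: float = 0.05) -> float:
    """Power of a two-sided two-sample t-test with n per group, via the
    noncentral-t distribution."""
    if n_per_group < 2:
        return 0.0
    df = 2 * n_per_group - 2
    nc = delta / (sd * math.sqrt(2.0 / n_per_group))
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def sample_size_per_group(delta: float, sd: float, power: float = 0.80,
                          alpha: float = 0.05) -> int:
    """Smallest integer n per group for which a two-sided two-sample
    t-test detects an absolute mean difference ``delta`` (common SD
    ``sd``) with at least the requested power, found by iterating the
    noncentral-t power evaluation upward from n = 2."""
    if delta <= 0 or sd <= 0:
        raise AgreementError("delta and sd must be positive")
    if not (0.0 < power < 1.0) or not (0.0 < alpha < 1.0):
        raise AgreementError("power and alpha must lie in (0, 1)")
    n = 2
    while power_two_sample_t(n, delta, sd, alpha) < power:
        n += 1
        if n > 10_000_000:  # pragma: no cover
            raise AgreementError("sample size did not converge")
    return n


def sample_size_table(deltas=(10, 15, 20, 25, 30),
                      powers=(0.80, 0.90, 0.95),
                      sd: float = 18.75,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Per-group sample sizes over a grid of detectable differences
    (percentage points of mean valvular activity) and power levels,
    at a common SD of 18.75 percentage points by default."""
    data = {f"power_{p:.2f}": [sample_size_per_group(d, sd, p, alpha) for d in deltas]
            for p in powers}
    return pd.DataFrame(data, index=pd.Index(list(deltas), name="delta_percent"))


# ---------------------------------------------------------------------------
# CSV-level helpers for paired metric tables


def pairs_from_table(df: pd.DataFrame, metric: str,
                     subject_col: str = "subject", repeat_col: str = "scan",
                     value_col: str | None = None) -> PairedMeasurements:
    """Extract aligned measurement pairs for one metric from a long-format
    table with subject ids, a repeat label taking two values, and either
    a ``metric``/``value`` pair of columns or one column per metric."""
    if value_col is None and "metric" in df.columns:
        df = df[df["metric"] == metric]
        value_col = "value"
    elif value_col is None:
        value_col = metric
    labels = sorted(df[repeat_col].unique())
    if len(labels) != 2:
        raise AgreementError(f"{repeat_col} must take exactly 2 values, got {labels}")
    wide = df.pivot_table(index=subject_col, columns=repeat_col,
                          values=value_col, aggfunc="first").dropna()
    return PairedMeasurements(wide[labels[0]].to_numpy(),
                              wide[labels[1]].to_numpy(), metric=metric)
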