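"""Agreement statistics for paired volume measurements.

Lin's concordance correlation coefficient (CCC) quantifies how well paired
measurements (x_i, y_i) fall on the identity line y = x. With moment
estimators (1/n by default, Lin's original form)

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (x̄ − ȳ)^2),

it penalizes both scatter around the best-fit line (precision, the Pearson
r) and systematic location/scale shifts away from identity (accuracy). The
95% confidence interval uses the Fisher z-transform of the CCC with its
asymptotic standard error, back-transformed — the standard inference for
this coefficient.

The module also provides the ordinary least-squares determination
coefficient R², median/range/IQR summaries, and the pooled-variance
two-sample t-test used to compare dose percent changes between treatment
approaches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PairedSample",
    "AgreementResult",
    "MedianSummary",
    "TTestResult",
    "lin_ccc",
    "r_squared",
    "median_summary",
    "approach_comparison",
]


@dataclass(frozen=True)
class PairedSample:
    """Paired measurements (x against the reference y), absent x dropped.

    Build with :meth:`from_pairs` to drop pairs whose x is missing while
    recording how many were dropped (e.g. patients without an evaluable
    CBCT volume).
    """

    x: np.ndarray
    y: np.ndarray
    labels: tuple = ()
    n_dropped: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ValueError("x and y must be 1-D and equal length")
        if len(self.x) < 3:
            raise ValueError("paired sample needs n >= 3")

    @classmethod
    def from_pairs(
        cls,
        x: Sequence[Optional[float]],
        y: Sequence[float],
        labels: Sequence = (),
    ) -> "PairedSample":
        labels = tuple(labels) if labels else tuple(range(1, len(list(y)) + 1))
        xs, ys, ls, dropped = [], [], [], 0
        for xi, yi, li in zip(x, y, labels, strict=True):
            if xi is None or (isinstance(xi, float) and math.isnan(xi)):
                dropped += 1
                continue
            xs.append(float(xi))
            ys.append(float(yi))
            ls.append(li)
        return cls(np.array(xs), np.array(ys), tuple(ls), dropped)

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class AgreementResult:
    """CCC with 95% CI, OLS R², and the pair count for one comparison."""

    ccc: float
    ci_low: float
    ci_high: float
    r2: float
    n: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.ccc <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


class MedianSummary(NamedTuple):
    median: float
    min: float
    max: float
    iqr: float


class TTestResult(NamedTuple):
    statistic: float
    p_value: float
    significant: bool  # at p < 0.05


def _moments(x: np.ndarray, y: np.ndarray, ddof: int) -> tuple[float, float, float, float, float]:
    mx, my = float(x.mean()), float(y.mean())
    n = len(x)
    d = n - ddof
    sx2 = float(((x - mx) ** 2).sum()) / d
    sy2 = float(((y - my) ** 2).sum()) / d
    sxy = float(((x - mx) * (y - my)).sum()) / d
    return mx, my, sx2, sy2, sxy


def lin_ccc(sample: PairedSample, *, bias_corrected: bool = False) -> AgreementResult:
    """Lin's concordance correlation coefficient with its 95% CI.

    Parameters
    ----------
    sample
        The paired measurements.
    bias_corrected
        Use 1/(n-1) moment estimators instead of the default 1/n form.
        At n ≈ 20 the two differ only in the second decimal.

    Raises
    ------
    ValueError
        If both sequences are constant and equal (the coefficient is the
        undefined ratio 0/0).
    """
    x, y = sample.x, sample.y
    n = sample.n
    ddof = 1 if bias_corrected else 0
    mx, my, sx2, sy2, sxy = _moments(x, y, ddof)
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        raise ValueError("CCC undefined: both sequences constant and equal")
    ccc = 2.0 * sxy / denom

    r2 = _ols_r2(x, y)

    if np.array_equal(x, y):
        # perfect concordance: degenerate CI
        return AgreementResult(1.0, 1.0, 1.0, r2, n, sample.n_dropped)

    ci_low, ci_high = _ccc_fisher_ci(ccc, x, y, n)
    ci_low = min(ci_low, ccc)
    ci_high = max(ci_high, ccc)
    return AgreementResult(ccc, ci_low, ci_high, r2, n, sample.n_dropped)


def _ccc_fisher_ci(ccc: float, x: np.ndarray, y: np.ndarray, n: int) -> tuple[float, float]:
    """Asymptotic 95% CI via the Fisher z-transform (Lin's variance)."""
    if abs(ccc) >= 1.0 or n <= 2:
        return ccc, ccc
    mx, my, sx2, sy2, _ = _moments(x, y, ddof=0)
    sx, sy = math.sqrt(sx2), math.sqrt(sy2)
    if sx == 0.0 or sy == 0.0:
        return ccc, ccc  # Pearson r undefined; no asymptotic variance
    r = float(np.corrcoef(x, y)[0, 1])
    if r == 0.0:
        return -1.0, 1.0
    u = (mx - my) / math.sqrt(sx * sy)
    c2 = ccc * ccc
    one_m = 1.0 - c2
    var_z = (
        (1.0 - r * r) * c2 / (one_m * r * r)
        + 4.0 * ccc**3 * (1.0 - ccc) * u * u / (r * one_m**2)
        - 2.0 * ccc**4 * u**4 / (r * r * one_m**2)
    ) / (n - 2)
    var_z = max(var_z, 0.0)
    z = math.atanh(ccc)
    half = 1.959963984540054 * math.sqrt(var_z)
    return math.tanh(z - half), math.tanh(z + half)


def _ols_r2(x: np.ndarray, y: np.ndarray) -> float:
    if np.all(x == x[0]):
        return float("nan")
    res = stats.linregress(x, y)
    return float(res.rvalue**2)


def r_squared(sample: PairedSample) -> float:
    """R² of the ordinary least-squares fit y ~ intercept + slope·x."""
    if np.all(sample.x == sample.x[0]):
        raise ValueError("R² undefined for constant x")
    return _ols_r2(sample.x, sample.y)


def median_summary(values: Sequence[float]) -> MedianSummary:
    """Median (midpoint convention for even n), min-max range and IQR."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("median_summary of empty list")
    q1, q3 = np.percentile(v, [25, 75])
    return MedianSummary(float(np.median(v)), float(v.min()), float(v.max()), float(q3 - q1))


def approach_comparison(
    percent_changes: Sequence[float], group_flags: Sequence[bool]
) -> TTestResult:
    """Pooled-variance two-sample t-test of percent changes between groups.

    ``group_flags`` marks membership of the lobar/total group; the test
    compares flagged against unflagged values. Significance is declared at
    p < 0.05.
    """
    pc = np.asarray(list(percent_changes), dtype=float)
    flags = np.asarray(list(group_flags), dtype=bool)
    if pc.shape != flags.shape:
        raise ValueError("percent_changes and group_flags must align")
    a, b = pc[flags], pc[~flags]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(t), float(p), bool(p < 0.05))
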