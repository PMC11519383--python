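"""Group comparisons for alignment/density/kinetics outputs.

Donor-matched designs (irradiated vs non-irradiated sites of the same
person) call for the paired t-test; the relationship between a metric and
the months elapsed since radiotherapy is summarized by Pearson
correlation. Tests are two-tailed throughout and no multiplicity
correction is applied — these are a handful of planned comparisons, not a
screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = ["SampleMeta", "PairedTestResult", "CorrelationResult",
           "paired_difference", "correlation_with_time",
           "DegenerateTestError"]

SITES = ("RT+", "RT-", "HS", "IR+", "IR-", "Ctr")


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: donor, site group, and optional covariates."""

    donor_id: str
    site: str
    months_since_rt: float | None = None
    timepoint: float | None = None

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}, got {self.site!r}")


class DegenerateTestError(ValueError):
    """Raised when a test statistic is undefined (zero variance, constant input)."""


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p_value: float
    n: int
    mean_difference: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


def paired_difference(values_a, values_b) -> PairedTestResult:
    """Classical paired t-test of per-donor metric pairs.

    The statistic is mean(d)/(sd(d)/√n) on the differences d = a − b with
    the sample (n−1) standard deviation; the two-tailed p comes from the
    t distribution with n−1 degrees of freedom.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise DegenerateTestError("paired t-test requires n ≥ 2 pairs")
    d = a - b
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        if mean_d == 0:
            # identical vectors: difference is exactly zero everywhere
            return PairedTestResult(statistic=0.0, p_value=1.0, n=n,
                                    mean_difference=0.0)
        raise DegenerateTestError(
            "differences have zero variance; t statistic undefined"
        )
    t = mean_d / (sd / np.sqrt(n))
    p = 2.0 * float(_sps.t.sf(abs(t), df=n - 1))
    return PairedTestResult(statistic=float(t), p_value=p, n=n,
                            mean_difference=mean_d)


def correlation_with_time(metric, months_since_rt) -> CorrelationResult:
    """Pearson correlation between a per-sample metric and months since RT.

    Two-tailed p from the t transform t = r√(n−2)/√(1−r²) with n−2
    degrees of freedom.
    """
    x = np.asarray(metric, dtype=float)
    y = np.asarray(months_since_rt, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("metric and months must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("Pearson correlation requires n ≥ 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateTestError("constant input: correlation undefined")
    res = _sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue),
                             n=x.size)
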