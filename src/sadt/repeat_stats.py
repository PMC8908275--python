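"""Nonparametric agreement and test-retest repeatability statistics.

Median ADC within the VTV is the measurement of interest; because such
data are typically non-normal, agreement between paired measurements is
summarized with nonparametric Bland-Altman statistics: the bias is the
median of the paired differences and the 68.3% limits of agreement
(LOA) are the 15.9% and 84.2% percentiles of the differences — the
order-statistic analogue of a +/- 1 SD interval for normal data.

The test-retest uncertainty u pools all test-retest differences,
symmetrizes them (each difference enters as both +d and -d, forcing a
zero-median distribution), and reports half the range between the
15.9% and 84.2% percentiles of the symmetrized sample, presented as
+/- u. A measured change is called significant when it exceeds u in
magnitude.

Percentiles use linear interpolation between closest ranks (position
1 + p*(n-1) on the sorted sample); the convention is echoed in every
summary for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

PCTL_LOW = 0.159
PCTL_HIGH = 0.842


@dataclass
class PairedMeasurements:
    """Per-subject pairs of scalar measurements (e.g. median ADC)."""

    ids: list
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        self.ids = list(self.ids)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if not (len(self.ids) == self.a.size == self.b.size):
            raise ValueError(
                f"ids/a/b lengths differ: {len(self.ids)}/{self.a.size}/{self.b.size}"
            )
        if self.a.size < 2:
            raise ValueError("need at least 2 pairs")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("subject ids must be unique")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))):
            raise ValueError("measurements must be finite")

    @property
    def n(self) -> int:
        return self.a.size

    @property
    def differences(self) -> np.ndarray:
        return self.a - self.b

    @property
    def means(self) -> np.ndarray:
        return 0.5 * (self.a + self.b)


@dataclass
class BlandAltmanSummary:
    """Bias (median difference) and nonparametric limits of agreement."""

    bias: float
    loa_low: float
    loa_high: float
    n: int
    percentiles: tuple[float, float] = (PCTL_LOW, PCTL_HIGH)

    def __post_init__(self):
        if not self.loa_low <= self.bias <= self.loa_high:
            raise ValueError("LOA must bracket the bias")


def percentile(values, p: float) -> float:
    """Order-statistic percentile with linear rank interpolation.

    Evaluates the sorted sample at position 1 + p*(n-1) (1-based),
    interpolating linearly between the two closest order statistics.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty collection")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"percentile fraction must lie in [0, 1], got {p}")
    return float(np.quantile(values, p, method="linear"))


def bland_altman(
    pairs: PairedMeasurements,
    percentiles: tuple[float, float] = (PCTL_LOW, PCTL_HIGH),
) -> BlandAltmanSummary:
    """Nonparametric Bland-Altman summary of paired differences a - b."""
    d = pairs.differences
    return BlandAltmanSummary(
        bias=float(np.median(d)),
        loa_low=percentile(d, percentiles[0]),
        loa_high=percentile(d, percentiles[1]),
        n=pairs.n,
        percentiles=tuple(percentiles),
    )


def pearson_with_ci(
    pairs: PairedMeasurements, level: float = 0.95
) -> tuple[float, float, float]:
    """Sample Pearson r with a Fisher-z confidence interval.

    The CI is tanh(arctanh(r) +/- q / sqrt(n - 3)) with q the standard
    normal quantile for the requested two-sided level.
    """
    if pairs.n < 4:
        raise ValueError(f"need >=4 pairs for a Fisher-z CI, got {pairs.n}")
    if np.var(pairs.a) == 0 or np.var(pairs.b) == 0:
        raise ValueError("correlation undefined: zero variance in a coordinate")
    r = float(sps.pearsonr(pairs.a, pairs.b).statistic)
    q = float(sps.norm.ppf(0.5 * (1 + level)))
    with np.errstate(divide="ignore"):
        z = np.arctanh(r)
    half = q / np.sqrt(pairs.n - 3)
    return r, float(np.tanh(z - half)), float(np.tanh(z + half))


def symmetrize(diffs) -> np.ndarray:
    """The multiset {+d} ∪ {-d}: zero-median by construction."""
    diffs = np.asarray(diffs, dtype=float).ravel()
    if diffs.size == 0:
        raise ValueError("empty collection of differences")
    if not np.all(np.isfinite(diffs)):
        raise ValueError("differences must be finite")
    return np.concatenate([diffs, -diffs])


def testretest_uncertainty(
    diffs, percentiles: tuple[float, float] = (PCTL_LOW, PCTL_HIGH)
) -> float:
    """Test-retest uncertainty +/- u from pooled paired differences.

    u is half the range between the low and high percentiles of the
    symmetrized difference distribution; for large normal noise with
    SD sigma, u converges to sigma.
    """
    sym = symmetrize(diffs)
    return 0.5 * (percentile(sym, percentiles[1]) - percentile(sym, percentiles[0]))


def significant_change(delta: float, u: float) -> bool:
    """True iff a measured change exceeds the uncertainty: |delta| > u."""
    if u < 0:
        raise ValueError("uncertainty must be >= 0")
    return bool(abs(delta) > u)
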