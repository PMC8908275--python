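"""Voxel-wise ADC mapping from multi-b-value DWI.

The apparent diffusion coefficient is the decay rate of the
mono-exponential signal model

    S(b) = S0 * exp(-b * ADC)

so ln S is linear in b with slope -ADC. The standard clinical two-point
estimate from a low/high b-value pair is

    ADC = ln(S_low / S_high) / (b_high - b_low)

which coincides with the ordinary-least-squares fit of ln S on b when
exactly two b-values are used. The default pair is (170, 1100) s·mm^-2:
the nonzero low b avoids perfusion (IVIM) contamination, the high b
gives diffusion sensitivity.

Voxels with any nonpositive selected signal get NaN rather than a
clamped value — clamping would fabricate diffusivities and bias the
median/SD statistics the delineation thresholds are built from.
Negative fitted ADCs are likewise retained, not floored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GridError
from .imaging_io import DwiSeries, ImageGrid

DEFAULT_B_LOW = 170.0
DEFAULT_B_HIGH = 1100.0


@dataclass
class AdcMap:
    """3D apparent-diffusion-coefficient map in mm^2·s^-1.

    ``values`` may contain NaN at voxels where the fit was undefined
    (nonpositive signal). ``blow``/``bhigh`` record the extreme
    b-values used by the fit.
    """

    values: np.ndarray
    grid: ImageGrid
    blow: float
    bhigh: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridError(
                f"ADC shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not self.blow < self.bhigh:
            raise ValueError(f"need blow < bhigh, got ({self.blow}, {self.bhigh})")

    @property
    def n_nonfinite(self) -> int:
        return int(np.count_nonzero(~np.isfinite(self.values)))


def _mean_volume_at(series: DwiSeries, bvalue: float) -> np.ndarray:
    idx = series.volumes_at(bvalue)
    if idx.size == 0:
        raise LookupError(
            f"b={bvalue} s/mm^2 not present in series; available b-values: "
            f"{sorted(set(series.bvalues.tolist()))}"
        )
    return series.signal[..., idx].mean(axis=3)


def fit_adc_two_point(
    series: DwiSeries,
    blow: float = DEFAULT_B_LOW,
    bhigh: float = DEFAULT_B_HIGH,
) -> AdcMap:
    """Closed-form two-point ADC: ln(S_low/S_high) / (b_high - b_low).

    Repeated volumes at either b-value are arithmetically averaged
    first (mirroring scanner averaging). Voxels where either signal is
    nonpositive are set to NaN.
    """
    if not blow < bhigh:
        raise ValueError(f"need blow < bhigh, got ({blow}, {bhigh})")
    s_low = _mean_volume_at(series, blow)
    s_high = _mean_volume_at(series, bhigh)
    valid = (s_low > 0) & (s_high > 0)
    adc = np.full(s_low.shape, np.nan)
    adc[valid] = np.log(s_low[valid] / s_high[valid]) / (bhigh - blow)
    return AdcMap(adc, series.grid, float(blow), float(bhigh))


def fit_adc_loglinear(series: DwiSeries, bvalues_to_use) -> AdcMap:
    """Per-voxel OLS of ln(S) on b over the selected b-values; ADC = -slope.

    With exactly two b-values this equals :func:`fit_adc_two_point` up
    to float tolerance. Repeated volumes per b-value are averaged
    before the fit. Voxels with any nonpositive selected signal get NaN.
    """
    bvals = np.unique(np.asarray(bvalues_to_use, dtype=float))
    if bvals.size < 2:
        raise ValueError(f"need >=2 distinct b-values for a log-linear fit, got {bvals.size}")
    stack = np.stack([_mean_volume_at(series, b) for b in bvals], axis=-1)
    valid = np.all(stack > 0, axis=-1)
    log_s = np.full(stack.shape, np.nan)
    log_s[valid] = np.log(stack[valid])
    # OLS slope = cov(b, lnS) / var(b), vectorized across voxels
    b_centered = bvals - bvals.mean()
    denom = float(np.sum(b_centered**2))
    slope = np.tensordot(log_s, b_centered, axes=([-1], [0])) / denom
    adc = np.where(valid, -slope, np.nan)
    return AdcMap(adc, series.grid, float(bvals[0]), float(bvals[-1]))


def average_repeated_bvalues(series: DwiSeries) -> DwiSeries:
    """Collapse repeated volumes per b-value to their arithmetic mean.

    Returns a series with one volume per distinct b-value, in
    ascending b order.
    """
    bvals = np.unique(series.bvalues)
    volumes = [series.signal[..., series.volumes_at(b)].mean(axis=3) for b in bvals]
    return DwiSeries(np.stack(volumes, axis=-1), bvals, series.grid)
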