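"""Semi-automatic delineation of viable tumour volume (VTV).

Starting from a rough manual mask drawn over the tumour region, the
tool extracts the viable (non-necrotic) tumour as the voxels that are
simultaneously bright on the high-b-value DWI image and low in ADC:

1. statistics are collected only inside the manual mask;
2. two thresholds are derived from those statistics — an Otsu threshold
   on the high-b intensities (bright voxels) and ``median + k*SD`` on
   the ADC values (low-diffusivity voxels, k = 0.5 by default);
3. the intersection of both criteria within the manual mask is the raw
   VTV.

Post-processing keeps the largest connected component and then lets the
VTV grow beyond the manual mask into any connected voxel that still
satisfies both thresholds (thresholds stay frozen at their manual-mask
estimates — re-estimating during growth would be circular). The
inclusive comparisons (DWI >= t, ADC <= t) keep the median voxels when
the in-mask spread degenerates to zero.

The joint criterion rejects necrosis (high ADC) and T2 shine-through
(bright at high b but not diffusion-restricted, hence high ADC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .adc_fit import AdcMap
from .errors import DegenerateHistogramError, EmptyDelineationError, GridError
from .imaging_io import BinaryMask, DwiSeries


@dataclass
class SadtConfig:
    """Tunables of the delineation tool.

    adc_sd_multiplier : ADC threshold is median + multiplier*SD of the
        in-mask ADC values; 0.5 gives a stable delineation.
    connectivity : 6 (faces only) or 26 (faces+edges+corners) voxel
        neighbourhood, used for components and expansion.
    otsu_bins : histogram bins for the Otsu threshold.
    expansion_enabled : allow the VTV to grow beyond the manual mask.
    slice_restricted_expansion : confine growth to slices the manual
        mask touches (useful when comparing against slice-limited
        manual contours).
    """

    adc_sd_multiplier: float = 0.5
    connectivity: int = 26
    otsu_bins: int = 256
    expansion_enabled: bool = True
    slice_restricted_expansion: bool = False

    def __post_init__(self):
        if self.adc_sd_multiplier < 0:
            raise ValueError("adc_sd_multiplier must be >= 0")
        if self.otsu_bins < 2:
            raise ValueError("otsu_bins must be >= 2")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")

    @property
    def structure(self) -> np.ndarray:
        """Binary structuring element matching the connectivity."""
        return ndimage.generate_binary_structure(3, 1 if self.connectivity == 6 else 3)


@dataclass
class DelineationResult:
    """Final VTV plus the intermediates needed to audit a delineation."""

    vtv: BinaryMask
    raw_vtv: BinaryMask
    dwi_mask: BinaryMask
    adc_mask: BinaryMask
    dwi_threshold: float
    adc_threshold: float
    median_adc: float
    vtv_volume_mm3: float
    expansion_voxels_added: int
    stage_voxel_counts: dict = field(default_factory=dict)


def otsu_threshold(values, bins: int = 256) -> float:
    """Otsu's threshold over a 1-D collection of values.

    A histogram of ``bins`` equal-width bins is built over
    [min, max]; the returned threshold is the interior bin edge t that
    maximizes the between-class variance

        sigma_b^2(t) = w0 * w1 * (mu0 - mu1)^2

    of the split {v < t} / {v >= t}. Ties pick the smallest t, so the
    result is deterministic for fixed input.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot threshold an empty collection")
    if not np.all(np.isfinite(values)):
        raise ValueError("cannot threshold non-finite values")
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        raise DegenerateHistogramError(
            f"all {values.size} values equal {vmin}: no class separation exists"
        )
    counts, edges = np.histogram(values, bins=int(bins), range=(vmin, vmax))
    sums, _ = np.histogram(values, bins=int(bins), range=(vmin, vmax), weights=values)
    # candidate thresholds are the interior bin edges t = edges[i];
    # np.histogram bins are left-inclusive, so class 0 (bins [0, i)) is
    # exactly {v < t} and the class means below are means of the actual
    # sample values, not bin-center approximations.
    total = counts.sum()
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    moments = np.cumsum(sums)
    mu0 = np.divide(moments[:-1], w0, out=np.zeros_like(moments[:-1]), where=w0 > 0)
    mu1 = np.divide(
        moments[-1] - moments[:-1], w1, out=np.zeros_like(moments[:-1]), where=w1 > 0
    )
    sigma_b = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
    return float(edges[1 + int(np.argmax(sigma_b))])


def compute_dwi_mask(
    highb_volume: np.ndarray, manual: BinaryMask, bins: int = 256
) -> tuple[BinaryMask, float]:
    """Bright-voxel mask on the high-b image via Otsu inside the manual mask.

    The threshold is estimated from intensities within the manual mask
    only, but the resulting mask (intensity >= threshold) covers the
    whole volume so that expansion eligibility is defined everywhere.
    """
    highb_volume = np.asarray(highb_volume, dtype=float)
    if highb_volume.shape != manual.grid.shape:
        raise GridError(
            f"volume shape {highb_volume.shape} does not match mask grid {manual.grid.shape}"
        )
    if manual.n_voxels == 0:
        raise ValueError("manual mask is empty")
    threshold = otsu_threshold(highb_volume[manual.voxels], bins=bins)
    return BinaryMask(highb_volume >= threshold, manual.grid), threshold


def compute_adc_mask(
    adc: AdcMap, manual: BinaryMask, multiplier: float = 0.5
) -> tuple[BinaryMask, float]:
    """Low-ADC mask: ADC <= median + multiplier*SD of in-mask values.

    The median and sample standard deviation (n-1 denominator) are
    taken over the finite ADC values inside the manual mask; the mask
    itself covers the whole volume and excludes non-finite voxels.
    """
    adc.grid.require_compatible(manual.grid, what="manual mask")
    inside = adc.values[manual.voxels]
    finite = inside[np.isfinite(inside)]
    if finite.size < 2:
        raise ValueError(
            f"need >=2 finite ADC voxels inside the manual mask, got {finite.size}"
        )
    threshold = float(np.median(finite) + multiplier * np.std(finite, ddof=1))
    with np.errstate(invalid="ignore"):
        mask = (adc.values <= threshold) & np.isfinite(adc.values)
    return BinaryMask(mask, manual.grid), threshold


def intersect(a: BinaryMask, b: BinaryMask, restrict: BinaryMask) -> BinaryMask:
    """Voxel-wise AND of two masks within a restriction mask."""
    a.grid.require_compatible(b.grid, what="second mask")
    a.grid.require_compatible(restrict.grid, what="restriction mask")
    return BinaryMask(a.voxels & b.voxels & restrict.voxels, a.grid)


def largest_component(mask: BinaryMask, connectivity: int = 26) -> BinaryMask:
    """Largest connected component under the given voxel neighbourhood.

    Size ties are broken deterministically by the smallest linear index
    of a component's first voxel in array scan order.
    """
    structure = ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)
    labels, n = ndimage.label(mask.voxels, structure=structure)
    if n == 0:
        raise EmptyDelineationError("mask is empty: no component to retain")
    sizes = np.bincount(labels.ravel())[1:]
    best = sizes.max()
    # scipy labels components in scan order, so among equal-size
    # components the smallest label has the smallest first-voxel index
    winner = 1 + int(np.flatnonzero(sizes == best)[0])
    return BinaryMask(labels == winner, mask.grid)


def expand_vtv(seed: BinaryMask, eligible: BinaryMask, connectivity: int = 26) -> BinaryMask:
    """Grow a connected seed into every eligible voxel reachable from it.

    This is the fixed point of repeated one-ring dilation intersected
    with the eligibility mask — equivalently the union of connected
    components of ``eligible`` that touch the seed. Thresholds behind
    ``eligible`` are frozen; this function only propagates connectivity.
    """
    seed.grid.require_compatible(eligible.grid, what="eligibility mask")
    if seed.n_voxels == 0:
        raise ValueError("seed mask is empty")
    if np.any(seed.voxels & ~eligible.voxels):
        raise ValueError("seed must be a subset of the eligible mask")
    structure = ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)
    labels, _ = ndimage.label(eligible.voxels, structure=structure)
    touched = np.unique(labels[seed.voxels])
    return BinaryMask(np.isin(labels, touched[touched > 0]), seed.grid)


def median_adc(adc: AdcMap, roi: BinaryMask) -> float:
    """Median of the finite ADC values inside a region of interest.

    Even counts use the mean of the two central order statistics.
    """
    adc.grid.require_compatible(roi.grid, what="ROI")
    inside = adc.values[roi.voxels]
    finite = inside[np.isfinite(inside)]
    if finite.size == 0:
        raise ValueError("ROI contains no finite ADC voxel")
    return float(np.median(finite))


def delineate(
    series: DwiSeries,
    adc: AdcMap,
    manual: BinaryMask,
    config: SadtConfig | None = None,
    b_high: float | None = None,
    thresholds: tuple[float, float] | None = None,
) -> DelineationResult:
    """Run the full delineation: thresholds, intersection, post-processing.

    Parameters
    ----------
    series : DwiSeries
        Must contain the high-b volume (repeats are averaged).
    adc : AdcMap
        ADC map on the same grid.
    manual : BinaryMask
        Rough operator-drawn region; thresholds are estimated inside it.
    config : SadtConfig
        Tool settings; defaults reproduce the standard workflow.
    b_high : float
        High b-value to threshold on; defaults to ``adc.bhigh``.
    thresholds : (dwi_threshold, adc_threshold), optional
        Injection hook: skip estimation and apply the given frozen
        thresholds (used e.g. to verify idempotence of the masking).

    Raises
    ------
    EmptyDelineationError
        If no voxel satisfies both criteria inside the manual mask;
        the exception carries both thresholds for diagnostics.
    """
    config = config or SadtConfig()
    series.grid.require_compatible(adc.grid, what="ADC map")
    series.grid.require_compatible(manual.grid, what="manual mask")
    if b_high is None:
        b_high = adc.bhigh
    idx = series.volumes_at(b_high)
    if idx.size == 0:
        raise LookupError(
            f"b={b_high} not present in series; available: "
            f"{sorted(set(series.bvalues.tolist()))}"
        )
    highb = series.signal[..., idx].mean(axis=3)

    if thresholds is None:
        dwi_mask, dwi_t = compute_dwi_mask(highb, manual, bins=config.otsu_bins)
        adc_mask, adc_t = compute_adc_mask(adc, manual, multiplier=config.adc_sd_multiplier)
    else:
        dwi_t, adc_t = float(thresholds[0]), float(thresholds[1])
        dwi_mask = BinaryMask(highb >= dwi_t, manual.grid)
        with np.errstate(invalid="ignore"):
            adc_mask = BinaryMask(
                (adc.values <= adc_t) & np.isfinite(adc.values), manual.grid
            )

    raw_vtv = intersect(dwi_mask, adc_mask, manual)
    if raw_vtv.n_voxels == 0:
        raise EmptyDelineationError(
            f"no voxel inside the manual mask satisfies both criteria "
            f"(DWI >= {dwi_t:.6g}, ADC <= {adc_t:.6g})",
            dwi_threshold=dwi_t,
            adc_threshold=adc_t,
        )
    core = largest_component(raw_vtv, connectivity=config.connectivity)

    if config.expansion_enabled:
        eligible_voxels = dwi_mask.voxels & adc_mask.voxels
        if config.slice_restricted_expansion:
            on_slices = manual.voxels.any(axis=(0, 1))
            eligible_voxels = eligible_voxels & on_slices[np.newaxis, np.newaxis, :]
        eligible = BinaryMask(eligible_voxels, manual.grid)
        vtv = expand_vtv(core, eligible, connectivity=config.connectivity)
    else:
        vtv = core

    return DelineationResult(
        vtv=vtv,
        raw_vtv=raw_vtv,
        dwi_mask=dwi_mask,
        adc_mask=adc_mask,
        dwi_threshold=dwi_t,
        adc_threshold=adc_t,
        median_adc=median_adc(adc, vtv),
        vtv_volume_mm3=vtv.volume_mm3,
        expansion_voxels_added=vtv.n_voxels - core.n_voxels,
        stage_voxel_counts={
            "manual": manual.n_voxels,
            "dwi_mask": dwi_mask.n_voxels,
            "adc_mask": adc_mask.n_voxels,
            "raw_vtv": raw_vtv.n_voxels,
            "largest_component": core.n_voxels,
            "final_vtv": vtv.n_voxels,
        },
    )
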