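"""Synthetic multi-b-value DWI phantoms with known tissue compartments.

The generator paints geometric compartments (ellipsoids / boxes, placed
in millimetres) onto a voxel grid, later compartments overwriting
earlier ones ("painter's rule"). Each compartment carries a baseline
signal S0 and a diffusivity ADC, and the noiseless signal follows the
same mono-exponential decay the ADC fit assumes:

    S(b) = S0 * exp(-b * ADC)

Magnitude MR images carry Rician noise — the magnitude of a complex
Gaussian perturbation — so the noisy signal is

    S' = sqrt((S + n1)^2 + n2^2),   n1, n2 ~ N(0, sigma)

with a plain additive-Gaussian option retained for analytic checks.
SNR is quoted as S0(background) / sigma at b = 0.

The default grid emulates a pelvic DWI protocol: 1.82 x 1.82 mm^2
in-plane, 5.0 mm slice pitch (4.6 mm slices + 0.4 mm gap; the gap is
absorbed into z-spacing since delineation operates on the voxel
lattice), b-values {0, 170, 1100} s·mm^-2. The canonical tumour
phantom has a bright, low-ADC viable rim around a high-ADC necrotic
core inside homogeneous background tissue; its compartment parameters
are fixture defaults chosen inside the physiological range (ADC of
order 1e-3 mm^2·s^-1), not measured tissue values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import logging

import numpy as np
from scipy import ndimage

from .adc_fit import AdcMap
from .imaging_io import BinaryMask, DwiSeries, ImageGrid

logger = logging.getLogger(__name__)

DEFAULT_GRID = ImageGrid(shape=(64, 64, 24), spacing=(1.82, 1.82, 5.0))
DEFAULT_BVALUES = (0.0, 170.0, 1100.0)


@dataclass(frozen=True)
class Compartment:
    """A geometric tissue compartment.

    shape : "ellipsoid" or "box"; centre/semi-axes in mm (box
        semi-axes are half-widths).
    adc : diffusivity in mm^2·s^-1 (> 0).
    s0 : baseline signal at b = 0 (> 0), arbitrary units.
    """

    shape: str
    center_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]
    adc: float
    s0: float
    name: str = ""

    def __post_init__(self):
        if self.shape not in ("ellipsoid", "box"):
            raise ValueError(f"unknown compartment shape {self.shape!r}")
        if self.adc <= 0:
            raise ValueError("compartment ADC must be > 0")
        if self.s0 <= 0:
            raise ValueError("compartment S0 must be > 0")


@dataclass
class PhantomSpec:
    """Everything needed to generate one reproducible phantom."""

    grid: ImageGrid = DEFAULT_GRID
    compartments: tuple[Compartment, ...] = ()
    bvalues: tuple[float, ...] = DEFAULT_BVALUES
    noise_sigma: float = 0.0
    noise_model: str = "rician"  # or "gaussian"
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_model not in ("rician", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if not self.compartments:
            raise ValueError("phantom needs at least one compartment")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    adc_true: AdcMap
    s0_true: np.ndarray
    compartment_labels: np.ndarray  # 1-based compartment index per voxel, 0 = unpainted
    viable_mask: BinaryMask


def _voxel_centers_mm(grid: ImageGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(grid.shape, grid.spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _paint(grid: ImageGrid, compartments) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rasterize compartments; later ones overwrite earlier on overlap."""
    x, y, z = _voxel_centers_mm(grid)
    fov = [n * s for n, s in zip(grid.shape, grid.spacing)]
    labels = np.zeros(grid.shape, dtype=np.int32)
    adc = np.zeros(grid.shape)
    s0 = np.zeros(grid.shape)
    for k, comp in enumerate(compartments, start=1):
        c, a = comp.center_mm, comp.semiaxes_mm
        if any(c[i] - a[i] < 0 or c[i] + a[i] > fov[i] for i in range(3)):
            logger.warning(
                "compartment %d (%s) extends outside the field of view; clipped",
                k,
                comp.name or comp.shape,
            )
        if comp.shape == "ellipsoid":
            inside = (
                ((x - c[0]) / a[0]) ** 2 + ((y - c[1]) / a[1]) ** 2 + ((z - c[2]) / a[2]) ** 2
            ) <= 1.0
        else:
            inside = (
                (np.abs(x - c[0]) <= a[0])
                & (np.abs(y - c[1]) <= a[1])
                & (np.abs(z - c[2]) <= a[2])
            )
        labels[inside] = k
        adc[inside] = comp.adc
        s0[inside] = comp.s0
    return labels, adc, s0


def generate_phantom(
    spec: PhantomSpec, viable_index: int | None = None
) -> tuple[DwiSeries, PhantomTruth]:
    """Generate a noisy DWI series plus ground truth from a spec.

    ``viable_index`` flags which compartment (1-based paint order)
    counts as viable tumour in the truth. By default the
    second-to-last compartment when three or more exist (the typical
    background / rim / core layering), else the last.
    """
    labels, adc_true, s0_true = _paint(spec.grid, spec.compartments)
    bvals = np.asarray(spec.bvalues, dtype=float)
    signal = s0_true[..., np.newaxis] * np.exp(-bvals * adc_true[..., np.newaxis])
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        if spec.noise_model == "rician":
            n1 = rng.normal(0.0, spec.noise_sigma, signal.shape)
            n2 = rng.normal(0.0, spec.noise_sigma, signal.shape)
            signal = np.hypot(signal + n1, n2)
        else:
            signal = signal + rng.normal(0.0, spec.noise_sigma, signal.shape)
    series = DwiSeries(signal, bvals, spec.grid)
    if viable_index is None:
        n = len(spec.compartments)
        viable_index = n - 1 if n >= 3 else n
    truth = PhantomTruth(
        adc_true=AdcMap(
            np.where(labels > 0, adc_true, np.nan),
            spec.grid,
            float(bvals.min()),
            float(bvals.max()),
        ),
        s0_true=s0_true,
        compartment_labels=labels,
        viable_mask=BinaryMask(labels == viable_index, spec.grid),
    )
    return series, truth


def default_tumour_spec(
    seed: int = 0, noise_sigma: float = 0.0, rim_adc: float = 0.9e-3
) -> PhantomSpec:
    """Canonical tumour phantom spec: background, viable rim, necrotic core.

    Background tissue fills the field of view (ADC 1.4e-3 mm^2·s^-1,
    S0 600); a viable tumour rim (ADC ``rim_adc``, default 0.9e-3, S0
    1000 — bright at high b and low ADC) is painted as a full
    ellipsoid whose interior is then overwritten by a necrotic core
    (ADC 2.2e-3, S0 900), leaving a thick shell of viable tissue.
    """
    grid = DEFAULT_GRID
    center = tuple(0.5 * n * s for n, s in zip(grid.shape, grid.spacing))
    background = Compartment(
        "box",
        center_mm=center,
        semiaxes_mm=tuple(0.5 * n * s for n, s in zip(grid.shape, grid.spacing)),
        adc=1.4e-3,
        s0=600.0,
        name="background",
    )
    rim = Compartment(
        "ellipsoid", center_mm=center, semiaxes_mm=(24.0, 22.0, 20.0),
        adc=rim_adc, s0=1000.0, name="viable_rim",
    )
    core = Compartment(
        "ellipsoid", center_mm=center, semiaxes_mm=(13.0, 12.0, 10.0),
        adc=2.2e-3, s0=900.0, name="necrotic_core",
    )
    return PhantomSpec(
        grid=grid,
        compartments=(background, rim, core),
        bvalues=DEFAULT_BVALUES,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def default_tumour_phantom(
    seed: int = 0, noise_sigma: float = 0.0, rim_adc: float = 0.9e-3
) -> tuple[DwiSeries, PhantomTruth]:
    """Generate the canonical tumour phantom (viable rim is label 2)."""
    spec = default_tumour_spec(seed=seed, noise_sigma=noise_sigma, rim_adc=rim_adc)
    return generate_phantom(spec, viable_index=2)


def tumour_manual_mask(truth: PhantomTruth, margin_voxels: int = 3) -> BinaryMask:
    """Emulated operator input for the canonical tumour phantom.

    A generous rough mask: the whole tumour (viable rim + necrotic
    core, i.e. every compartment past the background) dilated by a few
    voxels into the surrounding tissue, the way an operator would
    over-draw a relevant region without following the tumour boundary.
    """
    tumour = truth.compartment_labels >= 2
    if margin_voxels > 0:
        tumour = ndimage.binary_dilation(tumour, iterations=margin_voxels)
    return BinaryMask(tumour, truth.viable_mask.grid)


def truncated_tumour_mask(
    truth: PhantomTruth, fraction: float = 0.3, margin_voxels: int = 3
) -> BinaryMask:
    """A deliberately incomplete manual mask missing part of the rim.

    Starts from :func:`tumour_manual_mask` and blanks the trailing
    x-planes covering ``fraction`` of the viable rim's x-extent —
    emulating an operator whose rough mask cuts off part of the
    tumour, the situation the expansion step exists to repair.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    mask = tumour_manual_mask(truth, margin_voxels=margin_voxels)
    rim_x = np.flatnonzero(truth.viable_mask.voxels.any(axis=(1, 2)))
    cut = rim_x[int(np.floor((1.0 - fraction) * rim_x.size))]
    voxels = mask.voxels.copy()
    voxels[cut:, :, :] = False
    return BinaryMask(voxels, mask.grid)


def make_testretest_pair(
    spec: PhantomSpec, seed: int, jitter_mm: float = 0.0, viable_index: int | None = None
) -> tuple[DwiSeries, DwiSeries, PhantomTruth]:
    """Two back-to-back acquisitions of the same phantom.

    The two series share the anatomy but carry independent noise
    realizations. ``jitter_mm`` applies an integer-voxel rigid shift
    (uniform within +/- jitter_mm per axis, periodic roll) to the
    second acquisition, emulating bulk motion / peristalsis between
    test and retest; the returned truth is aligned with the first
    acquisition.
    """
    if jitter_mm < 0:
        raise ValueError("jitter_mm must be >= 0")
    rng = np.random.default_rng(seed)
    seed_a, seed_b = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    series_a, truth = generate_phantom(replace(spec, seed=seed_a), viable_index=viable_index)
    series_b, _ = generate_phantom(replace(spec, seed=seed_b), viable_index=viable_index)
    if jitter_mm > 0:
        shift_vox = [
            int(np.round(rng.uniform(-jitter_mm, jitter_mm) / sp))
            for sp in spec.grid.spacing
        ]
        shifted = np.roll(series_b.signal, shift=shift_vox, axis=(0, 1, 2))
        series_b = DwiSeries(shifted, series_b.bvalues, spec.grid)
    return series_a, series_b, truth
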