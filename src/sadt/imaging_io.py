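"""NIfTI volume/mask IO, b-value tables, and grid compatibility.

All images in a run must live on one voxel grid: the tool delineates
directly on the DWI lattice and never resamples. :class:`ImageGrid`
captures that lattice (shape, spacing in mm, world orientation) and is
compared across inputs with tight tolerances so that header rounding
between tools does not spuriously reject matched data.

Voxel indexing is 0-based in (x, y, z) array order as stored; world
coordinates are only used to report physical volumes in mm^3.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError, GridError

logger = logging.getLogger(__name__)

# Header rounding differs across tools; these absolute tolerances accept
# that while still rejecting genuinely different grids.
SPACING_TOL_MM = 1e-3
ORIGIN_TOL_MM = 1e-3
DIRECTION_TOL = 1e-4


@dataclass(frozen=True)
class ImageGrid:
    """Voxel lattice: shape, spacing (mm) and world mapping.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis, all >= 1.
    spacing : tuple of float
        Millimetres per voxel along each axis, all > 0.
    direction : (3, 3) array
        Direction-cosine matrix mapping voxel axes to world axes.
    origin : (3,) array
        World coordinates (mm) of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "direction", np.asarray(self.direction, dtype=float))
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise GridError(f"grid shape must be three axes of >=1 voxels, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GridError(f"grid spacing must be three positive lengths, got {self.spacing}")
        if self.direction.shape != (3, 3) or abs(np.linalg.det(self.direction)) < 1e-12:
            raise GridError("direction matrix must be 3x3 with nonzero determinant")

    @property
    def voxel_volume_mm3(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (NIfTI convention)."""
        aff = np.eye(4)
        aff[:3, :3] = self.direction @ np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    @classmethod
    def from_affine(cls, shape, affine) -> "ImageGrid":
        affine = np.asarray(affine, dtype=float)
        rs = affine[:3, :3]
        spacing = np.linalg.norm(rs, axis=0)
        if np.any(spacing <= 0):
            raise GridError("affine encodes nonpositive voxel spacing")
        direction = rs / spacing
        return cls(tuple(shape[:3]), tuple(spacing), direction, affine[:3, 3])

    def compatible_with(self, other: "ImageGrid") -> bool:
        """Symmetric, reflexive geometry match within header tolerances."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, rtol=0, atol=SPACING_TOL_MM)
            and np.allclose(self.origin, other.origin, rtol=0, atol=ORIGIN_TOL_MM)
            and np.allclose(self.direction, other.direction, rtol=0, atol=DIRECTION_TOL)
        )

    def require_compatible(self, other: "ImageGrid", what: str = "input") -> None:
        if not self.compatible_with(other):
            raise GridError(
                f"{what} grid does not match reference grid: "
                f"shape {other.shape} vs {self.shape}, "
                f"spacing {other.spacing} vs {self.spacing}"
            )


@dataclass
class DwiSeries:
    """A 4D diffusion-weighted acquisition with per-volume b-values.

    ``signal`` is (x, y, z, volume); ``bvalues`` has one entry
    (s·mm^-2) per trailing-axis volume.
    """

    signal: np.ndarray
    bvalues: np.ndarray
    grid: ImageGrid

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.bvalues = np.atleast_1d(np.asarray(self.bvalues, dtype=float))
        if self.signal.ndim != 4:
            raise FormatError(f"DWI signal must be 4D, got {self.signal.ndim}D")
        if self.signal.shape[3] != self.bvalues.size:
            raise FormatError(
                f"volume count ({self.signal.shape[3]}) does not match "
                f"b-value count ({self.bvalues.size})"
            )
        if self.signal.shape[:3] != self.grid.shape:
            raise GridError(
                f"signal shape {self.signal.shape[:3]} does not match grid {self.grid.shape}"
            )
        if np.any(self.bvalues < 0):
            raise FormatError("b-values must be nonnegative")
        if not np.all(np.isfinite(self.signal)):
            raise FormatError("DWI signal contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[3]

    def volumes_at(self, bvalue: float, atol: float = 0.5) -> np.ndarray:
        """Indices of volumes acquired at ``bvalue`` (within ``atol``)."""
        return np.flatnonzero(np.abs(self.bvalues - bvalue) <= atol)


@dataclass
class BinaryMask:
    """3D boolean region on an :class:`ImageGrid`."""

    voxels: np.ndarray
    grid: ImageGrid

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise FormatError(f"mask must be 3D, got {self.voxels.ndim}D")
        if self.voxels.shape != self.grid.shape:
            raise GridError(
                f"mask shape {self.voxels.shape} does not match grid {self.grid.shape}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_mm3


def read_bvalues(path) -> np.ndarray:
    """Read a b-value table: FSL-style whitespace text or a JSON array."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        values = json.loads(text)
        if not isinstance(values, list):
            raise FormatError(f"{path}: JSON b-value file must contain an array")
    else:
        values = text.split()
    try:
        arr = np.asarray([float(v) for v in values], dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric b-value entry ({exc})") from exc
    if arr.size == 0:
        raise FormatError(f"{path}: empty b-value file")
    return arr


def read_dwi(volume_path, bvalues_path) -> DwiSeries:
    """Load a 4D NIfTI volume together with its b-value table."""
    img = nib.load(str(volume_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        # a single-volume acquisition may be stored 3D; promote it
        data = data[..., np.newaxis]
    if data.ndim != 4:
        raise FormatError(f"{volume_path}: expected a 4D DWI volume, got {data.ndim}D")
    bvals = read_bvalues(bvalues_path)
    if data.shape[3] != bvals.size:
        raise FormatError(
            f"{volume_path} has {data.shape[3]} volumes but {bvalues_path} "
            f"lists {bvals.size} b-values"
        )
    grid = ImageGrid.from_affine(data.shape, img.affine)
    return DwiSeries(data, bvals, grid)


def read_volume(path) -> tuple[np.ndarray, ImageGrid]:
    """Load a 3D NIfTI scalar volume (e.g. an ADC map)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got {data.ndim}D")
    return data, ImageGrid.from_affine(data.shape, img.affine)


def read_mask(path, reference_grid: ImageGrid) -> BinaryMask:
    """Load a 3D NIfTI mask and check it sits on ``reference_grid``.

    Values outside {0, 1} are coerced to True with a logged warning
    (clinical masks are often exported as label maps). No resampling is
    performed: a geometry mismatch beyond header tolerance is an error.
    """
    data, grid = read_volume(path)
    if grid.shape != reference_grid.shape:
        raise GridError(
            f"{path}: mask shape {grid.shape} does not match reference {reference_grid.shape}"
        )
    reference_grid.require_compatible(grid, what=str(path))
    unique = np.unique(data)
    if not np.all(np.isin(unique, (0.0, 1.0))):
        logger.warning(
            "%s: mask values %s outside {0,1}; coercing nonzero to true",
            path,
            unique[:8],
        )
    return BinaryMask(data != 0, reference_grid)


def write_volume(array, grid: ImageGrid, path, dtype=None) -> None:
    """Write a 3D/4D array (or BinaryMask) to NIfTI on ``grid``.

    Boolean data are stored as uint8 so on-disk voxels are exactly
    {0, 1}; everything else defaults to float32.
    """
    if isinstance(array, BinaryMask):
        grid = array.grid
        array = array.voxels
    array = np.asarray(array)
    if array.shape[:3] != grid.shape:
        raise GridError(
            f"array shape {array.shape[:3]} does not match grid shape {grid.shape}"
        )
    if dtype is None:
        dtype = np.uint8 if array.dtype == bool else np.float32
    img = nib.Nifti1Image(array.astype(dtype), grid.affine)
    img.header.set_zooms(grid.spacing + ((1.0,) if array.ndim == 4 else ()))
    nib.save(img, str(path))
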