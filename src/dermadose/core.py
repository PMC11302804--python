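"""Shared voxel-grid and dose-map containers.

Conventions used throughout the package:

* 3D arrays are indexed ``[ix, iy, iz]`` with patient axes x = right-left,
  y = posterior-anterior (+y anterior/up), z = inferior-superior; lengths in cm.
* Grids use the voxel-centre convention: ``origin`` is the world position of
  voxel ``(0, 0, 0)``.
* 2D dose maps are indexed ``[row, col]``; rows run along the across-slice
  (superior -> inferior) unfolding coordinate, columns along the in-slice
  contour coordinate. All 2D doses are percent of the prescription dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy.interpolate import RegularGridInterpolator


class DermadoseError(Exception):
    """Base class for all package errors."""


class ConfigError(DermadoseError):
    pass


class GridSizeError(DermadoseError):
    pass


class GeometryError(DermadoseError):
    pass


class CalibrationError(DermadoseError):
    pass


class RegistrationError(DermadoseError):
    pass


class LatticeMismatchError(DermadoseError):
    pass


class FitError(DermadoseError):
    pass


@dataclass
class VoxelGrid:
    """Scalar field on a regular anisotropic voxel lattice (e.g. CT in HU)."""

    values: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def voxel_centers(self, mask: Optional[np.ndarray] = None) -> np.ndarray:
        """(N, 3) world coordinates of voxel centres, optionally masked."""
        if mask is None:
            idx = np.indices(self.shape).reshape(3, -1).T
        else:
            idx = np.argwhere(mask)
        return self.index_to_world(idx)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass
class StructureMask:
    """Binary voxel mask aligned to a :class:`VoxelGrid` lattice."""

    mask: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3D array")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.mask.shape

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_cc(self) -> float:
        return self.voxel_count * self.voxel_volume

    def grid(self) -> VoxelGrid:
        return VoxelGrid(self.mask.astype(np.uint8), self.spacing, self.origin)

    def same_lattice(self, other: "StructureMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def voxel_centers(self) -> np.ndarray:
        return self.grid().voxel_centers(self.mask)


@dataclass
class DoseGrid:
    """3D absorbed dose (Gy) with prescription metadata."""

    dose: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    prescription: float = 42.5
    label: str = ""

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.ndim != 3:
            raise ValueError("dose must be a 3D array")
        if self.prescription <= 0:
            raise ValueError("prescription must be positive")
        if np.any(self.dose < 0):
            raise ValueError("dose must be non-negative")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.dose.shape

    def grid(self) -> VoxelGrid:
        return VoxelGrid(self.dose, self.spacing, self.origin)

    def sample_percent(self, points: np.ndarray) -> np.ndarray:
        """Trilinear dose sample at world points, in percent of prescription.

        Raises :class:`GeometryError` if any point falls outside the lattice.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        axes = [self.grid().axis_coords(a) for a in range(3)]
        interp = RegularGridInterpolator(axes, self.dose, method="linear",
                                         bounds_error=True)
        try:
            gy = interp(points)
        except ValueError as exc:
            raise GeometryError(f"sample point outside dose grid: {exc}") from exc
        return 100.0 * gy / self.prescription


@dataclass
class RigidTransform2D:
    """2D rigid transform: rotation (deg, about the map centre) + translation (cm).

    Applying the transform to a moving map's coordinates aligns it with the
    fixed map: ``p_fixed = R(theta) @ (p_moving - c) + c + t`` with ``c`` the
    map centre and coordinates ``(x=col, y=row)`` in cm.
    """

    rotation_deg: float = 0.0
    translation: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not np.isfinite([self.rotation_deg, *self.translation]).all():
            raise ValueError("transform parameters must be finite")


@dataclass
class FilmDoseMap:
    """2D dose image in percent of prescription at film resolution.

    Both measured film and unfolded TPS dose use this container. ``valid_mask``
    marks pixels carrying dose; invalid pixels hold NaN by convention.
    """

    dose: np.ndarray
    pixel_spacing: float
    valid_mask: Optional[np.ndarray] = None
    provenance: str = ""
    # filled by the unfolding rasteriser: per-pixel index of the nearest source
    # surface sample, and the table of 3D source points
    source_index: Optional[np.ndarray] = None
    source_points: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.ndim != 2:
            raise ValueError("dose must be a 2D array")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.dose)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.dose.shape:
            raise ValueError("valid_mask shape must match dose shape")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.dose.shape

    @property
    def height_cm(self) -> float:
        return self.shape[0] * self.pixel_spacing

    @property
    def width_cm(self) -> float:
        return self.shape[1] * self.pixel_spacing

    def masked(self) -> np.ndarray:
        """Dose with NaN outside the valid mask."""
        out = self.dose.astype(float).copy()
        out[~self.valid_mask] = np.nan
        return out

    def valid_values(self) -> np.ndarray:
        return self.dose[self.valid_mask]

    def same_lattice(self, other: "FilmDoseMap") -> bool:
        return self.shape == other.shape and np.isclose(
            self.pixel_spacing, other.pixel_spacing
        )

    def copy_with(self, **kwargs) -> "FilmDoseMap":
        return replace(self, **kwargs)
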