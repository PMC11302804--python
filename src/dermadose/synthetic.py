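"""Synthetic phantom, dose-grid and film-measurement generation.

The phantom emulates a breast supported by a tilted cradle: the body is a
half-cylinder (flat face up, curved face down) whose axis is tilted by
``cradle_tilt`` degrees from the superior-inferior axis, resting in a thin
curved cradle shell that conforms to the underside over the contact arc. The
region where cradle and skin touch is the film measurement region; its
unfolded size is ``lateral_extent + inferior_extent`` along the axis and
``contact_area_target / (lateral_extent + inferior_extent)`` around the arc.

Dose grids use a closed-form buildup model instead of a radiation transport
calculation: with ``d`` the depth below the body surface,

    D(d) = Rx * [S + (1 - S) * (1 - exp(-d / lambda))] * (1 - k * exp(-d / lambda))

where ``S`` is the surface dose fraction, ``lambda`` the buildup length and
``k`` the lateral-scatter deficit applied only on the scatter (inferior) exit
surface. A signed first-voxel-layer bias and an optional uniform offset allow
algorithm-specific surface behaviour and controlled bias-injection studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .core import (
    ConfigError,
    DoseGrid,
    FilmDoseMap,
    GeometryError,
    GridSizeError,
    StructureMask,
    VoxelGrid,
)

HU_AIR = -1000.0
HU_BODY = 0.0
HU_CRADLE = -700.0  # inside the cradle threshold band [-800, -600]

DEFAULT_VOXEL_BUDGET = 40_000_000


@dataclass
class PhantomSpec:
    """Geometry and prescription of the synthetic breast-on-cradle phantom.

    Lengths in cm, angles in degrees, doses in Gy.
    """

    breast_radius: float = 4.0
    breast_length: float = 25.0  # superior-inferior extent along the cradle axis
    cradle_tilt: float = 12.0
    cradle_thickness: float = 0.3
    ct_spacing: Tuple[float, float, float] = (0.12, 0.12, 0.25)
    dose_grid_spacing: float = 0.1
    prescription: float = 42.5
    contact_area_target: float = 170.0
    lateral_extent: float = 11.0
    inferior_extent: float = 14.0
    margin: float = 0.6
    # the breast extends axially beyond the cradle so the contact region is
    # the curved band only, not the end caps
    body_overhang: float = 1.2

    def __post_init__(self) -> None:
        for name in ("breast_radius", "breast_length", "cradle_thickness",
                     "dose_grid_spacing", "prescription", "contact_area_target",
                     "lateral_extent", "inferior_extent"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.cradle_tilt < 90:
            raise ValueError("cradle_tilt must be in [0, 90) degrees")
        if any(s <= 0 for s in self.ct_spacing):
            raise ValueError("ct_spacing components must be positive")
        if self.contact_arc_angle > 0.95 * np.pi:
            raise ValueError(
                "contact_area_target too large for this breast radius/length"
            )

    @property
    def contact_length(self) -> float:
        """Unfolded contact-region length along the cradle axis (cm)."""
        return self.lateral_extent + self.inferior_extent

    @property
    def contact_width(self) -> float:
        """Unfolded contact-region width around the arc (cm)."""
        return self.contact_area_target / self.contact_length

    @property
    def contact_arc_angle(self) -> float:
        """Angular extent of the contact arc (radians)."""
        return self.contact_width / self.breast_radius


def _frame(spec: PhantomSpec):
    """Orthonormal frame: cradle axis and down-normal unit vectors."""
    t = np.deg2rad(spec.cradle_tilt)
    e_ax = np.array([0.0, np.sin(t), np.cos(t)])   # superior -> inferior, tilted
    n_dn = np.array([0.0, -np.cos(t), np.sin(t)])  # perpendicular, pointing down
    return e_ax, n_dn


def phantom_membership(spec: PhantomSpec, x, y, z):
    """Vectorised body/cradle membership test at world coordinates (cm).

    Returns ``(body, cradle, s)`` boolean arrays (broadcast) and the axial
    coordinate ``s`` along the cradle axis. The body is the half-cylinder
    below the tilted flat face; the cradle is a shell conforming to the body
    over the contact arc.
    """
    e_ax, n_dn = _frame(spec)
    s = y * e_ax[1] + z * e_ax[2]
    rn = y * n_dn[1] + z * n_dn[2]  # downward radial component
    rho = np.sqrt(np.asarray(x) ** 2 + rn ** 2)
    body = (
        (s >= -spec.body_overhang)
        & (s <= spec.breast_length + spec.body_overhang)
        & (rho <= spec.breast_radius)
        & (rn >= 0)
    )
    half = 0.5 * spec.contact_arc_angle
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_theta = np.where(rho > 0, rn / np.maximum(rho, 1e-12), 1.0)
    # the cradle is bounded by axial CT planes (z), not by planes normal to
    # its own tilted axis, so every CT slice carries a full contact arc
    t = np.deg2rad(spec.cradle_tilt)
    z_hi = spec.breast_length * np.cos(t)
    z_arr = np.broadcast_to(z, np.broadcast_shapes(np.shape(x), np.shape(y),
                                                   np.shape(z)))
    cradle = (
        (z_arr >= 0)
        & (z_arr <= z_hi)
        & (rho > spec.breast_radius)
        & (rho <= spec.breast_radius + spec.cradle_thickness)
        & (cos_theta >= np.cos(half))
    )
    return body, cradle, s


def _world_bounds(spec: PhantomSpec):
    t = np.deg2rad(spec.cradle_tilt)
    r_out = spec.breast_radius + spec.cradle_thickness
    m = spec.margin
    ov = spec.body_overhang
    xlo, xhi = -(spec.breast_radius + m), spec.breast_radius + m
    ylo = -r_out * np.cos(t) - ov * np.sin(t) - m
    yhi = (spec.breast_length + ov) * np.sin(t) + m
    zlo = -ov * np.cos(t) - m
    zhi = (spec.breast_length + ov) * np.cos(t) + r_out * np.sin(t) + m
    return (xlo, ylo, zlo), (xhi, yhi, zhi)


def _lattice(spec: PhantomSpec, spacing):
    lo, hi = _world_bounds(spec)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    shape = tuple(int(np.ceil((hi[a] - lo[a]) / spacing[a])) + 1 for a in range(3))
    origin = tuple(lo)
    return shape, tuple(spacing), origin


def generate_phantom_ct(
    spec: PhantomSpec, voxel_budget: int = DEFAULT_VOXEL_BUDGET
) -> Tuple[VoxelGrid, Dict[str, StructureMask]]:
    """Generate the phantom CT (HU) plus ground-truth body/cradle/air masks."""
    shape, spacing, origin = _lattice(spec, spec.ct_spacing)
    n_vox = int(np.prod(shape))
    if n_vox > voxel_budget:
        raise GridSizeError(
            f"CT grid of {n_vox} voxels exceeds the budget of {voxel_budget}"
        )
    xs = origin[0] + spacing[0] * np.arange(shape[0])
    ys = origin[1] + spacing[1] * np.arange(shape[1])
    zs = origin[2] + spacing[2] * np.arange(shape[2])
    body, cradle, _ = phantom_membership(
        spec,
        xs[:, None, None],
        ys[None, :, None],
        zs[None, None, :],
    )
    if not body.any():
        raise GeometryError("degenerate phantom: empty body")
    hu = np.full(shape, HU_AIR)
    hu[body] = HU_BODY
    hu[cradle] = HU_CRADLE
    ct = VoxelGrid(hu, spacing, origin)
    masks = {
        "body": StructureMask(body, spacing, origin, "body"),
        "cradle": StructureMask(cradle, spacing, origin, "cradle"),
        "air": StructureMask(~(body | cradle), spacing, origin, "air"),
    }
    return ct, masks


@dataclass
class AlgorithmProfile:
    """Parametric surface-dose behaviour of a dose engine.

    ``surface_bias`` is applied (as % of prescription) in the first voxel
    layer only; ``lateral_scatter_deficit`` scales dose down on the scatter
    (inferior) exit surface; ``global_bias`` is a uniform offset used for
    controlled bias-injection experiments.
    """

    name: str
    surface_dose_fraction: float = 0.85
    buildup_length: float = 1.0
    surface_bias: float = 0.0
    lateral_scatter_deficit: float = 0.0
    global_bias: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.surface_dose_fraction <= 1:
            raise ValueError("surface_dose_fraction must be in [0, 1]")
        if self.buildup_length <= 0:
            raise ValueError("buildup_length must be positive")


def default_profiles() -> Dict[str, AlgorithmProfile]:
    """Default dose-engine profiles.

    ``truth`` defines the synthetic ground truth the film measures. The
    AAA-like profile underestimates surface dose with a larger deficit on the
    scatter (inferior) surface; the AXB-like profile slightly overestimates.
    Magnitudes are generator conventions, not physics claims.
    """
    return {
        "truth": AlgorithmProfile("truth", 0.84, 1.0, 0.0, 0.0),
        "aaa_like": AlgorithmProfile("aaa_like", 0.79, 1.2, -1.0, 5.0),
        "axb_like": AlgorithmProfile("axb_like", 0.86, 1.0, 0.5, 1.0),
    }


def get_profile(name: str) -> AlgorithmProfile:
    profiles = default_profiles()
    if name not in profiles:
        raise ConfigError(
            f"unknown algorithm profile {name!r}; known: {sorted(profiles)}"
        )
    return profiles[name]


@dataclass
class DoseGeometry:
    """Cached per-phantom geometry shared by all dose-engine profiles."""

    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float]
    body: np.ndarray          # body mask on the dose lattice
    depth: np.ndarray         # depth below body surface (cm), 0 outside body
    first_layer: np.ndarray   # body-boundary voxels plus exterior
    scatter: np.ndarray       # scatter-surface (inferior) region


def compute_dose_geometry(spec: PhantomSpec, spacing: Optional[float] = None,
                          voxel_budget: int = DEFAULT_VOXEL_BUDGET) -> DoseGeometry:
    """Body mask and buildup depth on the dose lattice.

    Depth is the anisotropic Euclidean distance transform of the body mask,
    i.e. distance from each body voxel centre to the nearest non-body voxel
    centre.
    """
    if spacing is None:
        spacing = spec.dose_grid_spacing
    shape, spacing3, origin = _lattice(spec, spacing)
    n_vox = int(np.prod(shape))
    if n_vox > voxel_budget:
        raise GridSizeError(
            f"dose grid of {n_vox} voxels exceeds the budget of {voxel_budget}"
        )
    xs = origin[0] + spacing3[0] * np.arange(shape[0])
    ys = origin[1] + spacing3[1] * np.arange(shape[1])
    zs = origin[2] + spacing3[2] * np.arange(shape[2])
    body, _, _ = phantom_membership(
        spec,
        xs[:, None, None],
        ys[None, :, None],
        zs[None, None, :],
    )
    if not body.any():
        raise GeometryError("degenerate phantom: empty body on dose lattice")
    depth = ndimage.distance_transform_edt(body, sampling=spacing3)
    interior = ndimage.binary_erosion(
        body, structure=np.ones((3, 3, 3), bool), border_value=1
    )
    first_layer = ~interior
    # scatter (inferior) region: axial position past the lateral band, with
    # axial distance measured the way the unfolded map measures it
    t = np.deg2rad(spec.cradle_tilt)
    z_split = spec.lateral_extent * np.cos(t)
    scatter = np.broadcast_to(zs[None, None, :] > z_split, shape).copy()
    return DoseGeometry(shape, spacing3, origin, body, depth, first_layer, scatter)


def buildup_dose(depth, profile: AlgorithmProfile, prescription: float,
                 scatter=False, first_layer=False) -> np.ndarray:
    """Closed-form buildup dose (Gy) at depth ``depth`` cm below the surface."""
    depth = np.asarray(depth, dtype=float)
    s = profile.surface_dose_fraction
    lam = profile.buildup_length
    decay = np.exp(-depth / lam)
    dose = prescription * (s + (1.0 - s) * (1.0 - decay))
    dose = dose * (1.0 - (profile.lateral_scatter_deficit / 100.0) * decay *
                   np.asarray(scatter, dtype=float))
    dose = dose + prescription * (profile.surface_bias / 100.0) * np.asarray(
        first_layer, dtype=float
    )
    dose = dose + prescription * (profile.global_bias / 100.0)
    return np.clip(dose, 0.0, None)


def generate_dose_grid(
    spec: PhantomSpec,
    profile,
    geometry: Optional[DoseGeometry] = None,
    spacing: Optional[float] = None,
) -> DoseGrid:
    """TPS-like dose grid for one algorithm profile on the dose lattice."""
    if isinstance(profile, str):
        profile = get_profile(profile)
    if geometry is None:
        geometry = compute_dose_geometry(spec, spacing=spacing)
    dose = buildup_dose(
        geometry.depth,
        profile,
        spec.prescription,
        scatter=geometry.scatter,
        first_layer=geometry.first_layer,
    )
    return DoseGrid(dose, geometry.spacing, geometry.origin,
                    prescription=spec.prescription, label=profile.name)


@dataclass
class FilmNoiseModel:
    """Noise/artefact model for synthetic film measurements.

    Offsets and amplitudes are in percent of prescription; the ridge term is a
    sinusoid along the across-slice (row) direction emulating periodic
    reconstruction artefacts. Each fraction can carry a small random rigid
    misalignment to exercise registration.
    """

    systematic_offset: float = 0.0
    noise_sd: float = 0.0
    ridge_amplitude: float = 0.0
    ridge_period: float = 1.2
    seed: int = 0
    max_shift_cm: float = 0.0
    max_rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.ridge_amplitude != 0 and self.ridge_period <= 0:
            raise ValueError("ridge_period must be positive when ridges are on")


def generate_film_measurement(
    true_surface: FilmDoseMap,
    noise: FilmNoiseModel,
    n_fractions: int = 3,
    rng: Optional[np.random.Generator] = None,
) -> List[FilmDoseMap]:
    """Simulate per-fraction film dose maps from the true surface dose.

    Each map is the (optionally misaligned) truth plus the systematic offset,
    the ridge term and i.i.d. Gaussian noise. Reproducible from the model
    seed.
    """
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    from .film import resample_rigid  # local import to avoid a cycle

    rows = np.arange(true_surface.shape[0]) * true_surface.pixel_spacing
    if noise.ridge_amplitude != 0:
        ridge = noise.ridge_amplitude * np.sin(
            2.0 * np.pi * rows / noise.ridge_period
        )[:, None]
    else:
        ridge = 0.0
    maps = []
    for k in range(n_fractions):
        if noise.max_shift_cm > 0 or noise.max_rotation_deg > 0:
            from .core import RigidTransform2D

            shift = rng.uniform(-noise.max_shift_cm, noise.max_shift_cm, size=2)
            rot = rng.uniform(-noise.max_rotation_deg, noise.max_rotation_deg)
            warped = resample_rigid(
                true_surface, RigidTransform2D(rot, (shift[0], shift[1]))
            )
        else:
            warped = true_surface
        dose = warped.dose + noise.systematic_offset + ridge
        if noise.noise_sd > 0:
            dose = dose + rng.normal(0.0, noise.noise_sd, size=dose.shape)
        out = np.where(warped.valid_mask, dose, np.nan)
        maps.append(
            FilmDoseMap(
                out,
                true_surface.pixel_spacing,
                warped.valid_mask.copy(),
                provenance=f"film_fraction_{k + 1}",
            )
        )
    return maps
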