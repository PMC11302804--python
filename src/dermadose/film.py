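"""Radiochromic film processing: calibration, trimming, filtering,
registration of repeat fractions and averaging.

The processing chain mirrors common EBT3 practice: green-channel response is
converted to dose through a rational calibration curve, the outer two pixels
of the cut film are discarded, an adaptive (local mean/variance) noise filter
and a median filter with 5x5 windows suppress scanner noise, repeat-fraction
maps are rigidly registered to the first fraction and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, optimize

from .core import (
    CalibrationError,
    FilmDoseMap,
    LatticeMismatchError,
    RegistrationError,
    RigidTransform2D,
)

INCH_CM = 2.54


@dataclass
class FilmScanImage:
    """Scanned film image: RGB integer pixels plus scanner resolution."""

    pixels: np.ndarray
    dpi: float = 72.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] < 3:
            raise ValueError("pixels must be an RGB image (H, W, 3)")
        if self.pixels.size == 0:
            raise ValueError("image must be non-empty")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")

    @property
    def green(self) -> np.ndarray:
        return self.pixels[..., 1].astype(float)

    @property
    def pixel_spacing(self) -> float:
        return INCH_CM / self.dpi


@dataclass
class CalibrationCurve:
    """Rational response curve X(D) = (a + b D) / (c + D) for one colour channel."""

    a: float
    b: float
    c: float
    dose_range: Tuple[float, float] = (0.0, 10.0)
    residuals: Optional[np.ndarray] = None

    def response(self, dose) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        return (self.a + self.b * dose) / (self.c + dose)

    def dose(self, response) -> np.ndarray:
        """Inverse: D(X) = (a - c X) / (X - b)."""
        response = np.asarray(response, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            return (self.a - self.c * response) / (response - self.b)

    def response_range(self) -> Tuple[float, float]:
        lo, hi = self.response(self.dose_range[0]), self.response(self.dose_range[1])
        return (min(lo, hi), max(lo, hi))


def fit_calibration(doses: Sequence[float],
                    responses: Sequence[float]) -> CalibrationCurve:
    """Least-squares fit of the rational calibration form.

    The form is linear in (a, b, c) after rearrangement
    ``a + b D - c X = X D``, which provides the (exact for three noiseless
    points) starting estimate; a Levenberg-Marquardt refinement on response
    residuals follows.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.size != responses.size:
        raise CalibrationError("doses and responses must have equal length")
    order = np.argsort(doses)
    d, x = doses[order], responses[order]
    if np.unique(d).size < 3:
        raise CalibrationError("need at least 3 distinct dose levels")
    steps = np.diff(x)
    if not (np.all(steps > 0) or np.all(steps < 0)):
        raise CalibrationError("responses must be strictly monotone in dose")
    # linear solve of a + b*D - c*X = X*D
    A = np.column_stack([np.ones_like(d), d, -x])
    coef, *_ = np.linalg.lstsq(A, x * d, rcond=None)
    a0, b0, c0 = coef

    def model(dd, a, b, c):
        return (a + b * dd) / (c + dd)

    try:
        import warnings

        with warnings.catch_warnings():
            # an exactly-determined 3-point fit has no covariance estimate
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(model, d, x, p0=[a0, b0, c0],
                                         maxfev=10000)
    except RuntimeError as exc:
        raise CalibrationError(f"calibration fit did not converge: {exc}") from exc
    a, b, c = popt
    if np.any(np.abs(c + d) < 1e-9):
        raise CalibrationError("fitted curve has a pole inside the dose range")
    curve = CalibrationCurve(a, b, c, (float(d.min()), float(d.max())))
    curve.residuals = model(d, a, b, c) - x
    return curve


def apply_calibration(scan: FilmScanImage, curve: CalibrationCurve,
                      prescription: float) -> FilmDoseMap:
    """Convert a scan's green channel to dose in percent of prescription.

    Responses outside the calibrated range are masked invalid rather than
    clipped, to avoid fabricating dose.
    """
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    x = scan.green
    lo, hi = curve.response_range()
    valid = (x >= lo) & (x <= hi)
    dose_gy = curve.dose(x)
    pct = 100.0 * dose_gy / prescription
    pct = np.where(valid, pct, np.nan)
    return FilmDoseMap(pct, scan.pixel_spacing, valid, provenance="calibrated_scan")


def trim_edges(film: FilmDoseMap, n_pixels: int = 2) -> FilmDoseMap:
    """Erode the valid mask inward by ``n_pixels`` along its boundary.

    Removes every pixel within Chebyshev distance ``n_pixels`` of the mask
    complement (the image border counts as complement), discarding potential
    film-cutting artefacts.
    """
    if n_pixels < 0:
        raise ValueError("n_pixels must be non-negative")
    if n_pixels == 0:
        return film.copy_with(dose=film.dose.copy(), valid_mask=film.valid_mask.copy())
    if min(film.shape) <= 2 * n_pixels:
        raise ValueError("map too small to trim")
    size = 2 * n_pixels + 1
    eroded = ndimage.binary_erosion(
        film.valid_mask, structure=np.ones((size, size), bool), border_value=0
    )
    dose = np.where(eroded, film.dose, np.nan)
    return film.copy_with(dose=dose, valid_mask=eroded)


def _adaptive_wiener(image: np.ndarray, size: int = 5) -> np.ndarray:
    """Adaptive local mean/variance noise filter (edge-replicated windows).

    Classic pixel-wise Wiener filter: with local mean m and variance v over a
    ``size x size`` window and noise power estimated as the mean local
    variance, the output is ``m + max(v - n, 0) / v * (x - m)``; degenerate
    windows (v <= n, including constant images) return the local mean. Edge
    windows replicate the border pixel so constant maps are exact fixed
    points.
    """
    img = np.asarray(image, dtype=float)
    l_mean = ndimage.uniform_filter(img, size, mode="nearest")
    l_sq = ndimage.uniform_filter(img * img, size, mode="nearest")
    l_var = l_sq - l_mean * l_mean
    noise = float(l_var.mean())
    out = np.where(
        l_var > noise,
        l_mean + (img - l_mean) * (1.0 - noise / np.maximum(l_var, 1e-300)),
        l_mean,
    )
    return out


def _fill_invalid_nearest(dose: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Replace invalid pixels by their nearest valid neighbour's value."""
    if valid.all():
        return dose.astype(float).copy()
    idx = ndimage.distance_transform_edt(~valid, return_distances=False,
                                         return_indices=True)
    return dose[tuple(idx)]


def denoise(film: FilmDoseMap, size: int = 5,
            order: Tuple[str, str] = ("wiener", "median")) -> FilmDoseMap:
    """Apply the adaptive noise filter and the median filter (5x5 windows).

    Invalid pixels are filled with their nearest valid value before filtering
    so that masked-out regions do not bleed into the valid region; the output
    keeps the input mask. Maps smaller than the window pass through unchanged.
    """
    if min(film.shape) < size or film.valid_mask.sum() == 0:
        return film.copy_with(dose=film.dose.copy(), valid_mask=film.valid_mask.copy())
    work = _fill_invalid_nearest(np.where(film.valid_mask, film.dose, 0.0),
                                 film.valid_mask)
    for stage in order:
        if stage == "wiener":
            work = _adaptive_wiener(work, size)
        elif stage == "median":
            work = ndimage.median_filter(work, size=size, mode="nearest")
        else:
            raise ValueError(f"unknown filter stage {stage!r}")
    dose = np.where(film.valid_mask, work, np.nan)
    return film.copy_with(dose=dose, valid_mask=film.valid_mask.copy())


# ---------------------------------------------------------------------------
# rigid registration
# ---------------------------------------------------------------------------


def resample_rigid(film: FilmDoseMap, transform: RigidTransform2D) -> FilmDoseMap:
    """Resample a map under a rigid transform onto its own lattice.

    The transform maps moving coordinates into fixed coordinates (rotation
    about the map centre, then translation); the output is the moving map
    expressed in the fixed frame. Bilinear interpolation; pixels that map
    outside the source or touch invalid source pixels become invalid.
    """
    h, w = film.shape
    sp = film.pixel_spacing
    theta = np.deg2rad(transform.rotation_deg)
    ct, st = np.cos(theta), np.sin(theta)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    # fixed-frame (x, y) in pixels relative to centre, minus translation
    xf = cols - cx - transform.translation[0] / sp
    yf = rows - cy - transform.translation[1] / sp
    # inverse rotation back into the moving frame
    xm = ct * xf + st * yf + cx
    ym = -st * xf + ct * yf + cy
    coords = np.stack([ym, xm])
    filled = _fill_invalid_nearest(np.where(film.valid_mask, film.dose, 0.0),
                                   film.valid_mask)
    dose = ndimage.map_coordinates(filled, coords, order=1, mode="constant",
                                   cval=np.nan)
    vmask = ndimage.map_coordinates(film.valid_mask.astype(float), coords,
                                    order=1, mode="constant", cval=0.0)
    valid = (vmask > 0.999) & np.isfinite(dose)
    dose = np.where(valid, dose, np.nan)
    return film.copy_with(dose=dose, valid_mask=valid)


def _ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Normalised cross-correlation over a common valid mask."""
    if mask.sum() < 16:
        return -np.inf
    av = a[mask] - a[mask].mean()
    bv = b[mask] - b[mask].mean()
    denom = np.sqrt((av ** 2).sum() * (bv ** 2).sum())
    if denom == 0:
        return -np.inf
    return float((av * bv).sum() / denom)


def _translation_estimate(fixed: np.ndarray, fmask: np.ndarray,
                          moving: np.ndarray, mmask: np.ndarray) -> Tuple[float, float]:
    """Subpixel translation estimate (dy, dx) by phase cross-correlation.

    Returns the shift to apply to the moving image to align it with the
    fixed image, in pixels.
    """
    from skimage.registration import phase_cross_correlation

    f = np.where(fmask, fixed - fixed[fmask].mean(), 0.0) if fmask.any() else fixed
    m = np.where(mmask, moving - moving[mmask].mean(), 0.0) if mmask.any() else moving
    shift, _, _ = phase_cross_correlation(f, m, upsample_factor=10)
    return float(shift[0]), float(shift[1])


def register_rigid(
    moving: FilmDoseMap,
    fixed: FilmDoseMap,
    max_rotation_deg: float = 10.0,
    max_shift_cm: float = 1.5,
    coarse_angles: int = 21,
) -> Tuple[RigidTransform2D, FilmDoseMap]:
    """Rigid (rotation + translation) registration maximising masked NCC.

    Coarse stage: rotation sweep with FFT-based translation search at each
    angle. Fine stage: Nelder-Mead refinement of (rotation, tx, ty) on the
    bilinear-resampled NCC objective. Returns the transform and the moving
    map resampled onto the fixed lattice.
    """
    if not moving.same_lattice(fixed):
        raise LatticeMismatchError("maps must share shape and pixel spacing")
    sp = fixed.pixel_spacing
    fdose = np.where(fixed.valid_mask, fixed.dose, 0.0)

    best = (-np.inf, 0.0, 0.0, 0.0)
    for theta in np.linspace(-max_rotation_deg, max_rotation_deg, coarse_angles):
        rot = resample_rigid(moving, RigidTransform2D(theta, (0.0, 0.0)))
        rdose = np.where(rot.valid_mask, rot.dose, 0.0)
        dr, dc = _translation_estimate(fdose, fixed.valid_mask, rdose,
                                       rot.valid_mask)
        if np.hypot(dr, dc) * sp > max_shift_cm:
            dr, dc = 0.0, 0.0  # spurious lock; fall back to zero shift
        cand = RigidTransform2D(theta, (dc * sp, dr * sp))
        res = resample_rigid(moving, cand)
        score = _ncc(res.dose, fixed.dose, res.valid_mask & fixed.valid_mask)
        if score > best[0]:
            best = (score, theta, dc * sp, dr * sp)

    if not np.isfinite(best[0]):
        raise RegistrationError("no valid overlap between maps")

    def objective(p):
        theta, tx, ty = p
        res = resample_rigid(moving, RigidTransform2D(theta, (tx, ty)))
        return -_ncc(res.dose, fixed.dose, res.valid_mask & fixed.valid_mask)

    x0 = np.array(best[1:])
    result = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "xatol": 1e-3 * sp,
            "fatol": 1e-10,
            "maxiter": 600,
            "initial_simplex": x0 + np.vstack(
                [np.zeros(3), np.diag([0.5, 2.0 * sp, 2.0 * sp])]
            ),
        },
    )
    if not np.isfinite(result.fun):
        raise RegistrationError(
            f"registration failed to converge: best NCC not finite "
            f"(start={x0.tolist()}, nit={result.nit})"
        )
    theta, tx, ty = result.x
    transform = RigidTransform2D(float(theta), (float(tx), float(ty)))
    resampled = resample_rigid(moving, transform)
    return transform, resampled


def average_fractions(maps: List[FilmDoseMap]) -> FilmDoseMap:
    """Pixel-wise mean over co-registered maps; valid where all inputs are."""
    if len(maps) == 0:
        raise ValueError("need at least one map")
    first = maps[0]
    for m in maps[1:]:
        if not m.same_lattice(first):
            raise LatticeMismatchError("fraction maps must share the lattice")
    valid = np.logical_and.reduce([m.valid_mask for m in maps])
    stack = np.stack([np.where(m.valid_mask, m.dose, 0.0) for m in maps])
    mean = stack.mean(axis=0)
    dose = np.where(valid, mean, np.nan)
    return first.copy_with(dose=dose, valid_mask=valid,
                           provenance="mean_measured")


def resample_spacing(film: FilmDoseMap, new_spacing: float) -> FilmDoseMap:
    """Bilinear resample of a map onto a coarser/finer square lattice."""
    if new_spacing <= 0:
        raise ValueError("new_spacing must be positive")
    h, w = film.shape
    ratio = new_spacing / film.pixel_spacing
    nh = max(int(np.floor((h - 1) / ratio)) + 1, 2)
    nw = max(int(np.floor((w - 1) / ratio)) + 1, 2)
    rows = np.arange(nh) * ratio
    cols = np.arange(nw) * ratio
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    filled = _fill_invalid_nearest(np.where(film.valid_mask, film.dose, 0.0),
                                   film.valid_mask)
    dose = ndimage.map_coordinates(filled, np.stack([rr, cc]), order=1)
    vmask = ndimage.map_coordinates(film.valid_mask.astype(float),
                                    np.stack([rr, cc]), order=1)
    valid = vmask > 0.999
    return FilmDoseMap(np.where(valid, dose, np.nan), new_spacing, valid,
                       provenance=film.provenance)
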