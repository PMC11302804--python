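"""Pixel-wise calculated-minus-measured dose differences, pooled histograms,
Gaussian fits and between-algorithm significance testing.

The sign convention throughout is TPS minus film: negative means the
calculation underestimates the measurement. Histograms pool valid pixels
across all cases with 1%-of-prescription bins centred on integers, and a
Gaussian ``A * exp(-(x - mu)^2 / (2 sigma^2))`` is fitted to the bin counts
by nonlinear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .core import FilmDoseMap, FitError, GeometryError, LatticeMismatchError


@dataclass
class DoseDifferenceMap:
    """Calculated - measured dose (percent of prescription) with regions."""

    diff: np.ndarray
    valid_mask: np.ndarray
    pixel_spacing: float
    regions: Optional[Dict[str, np.ndarray]] = None

    def __post_init__(self) -> None:
        self.diff = np.asarray(self.diff, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.diff.shape != self.valid_mask.shape:
            raise ValueError("diff and valid_mask must share shape")

    def values(self, region: str = "full") -> np.ndarray:
        mask = self.valid_mask
        if self.regions is not None and region in self.regions:
            mask = mask & self.regions[region]
        elif region != "full":
            raise KeyError(f"unknown region {region!r}")
        return self.diff[mask]


@dataclass
class GaussianFit:
    """Gaussian fitted to histogram counts."""

    mean: float
    sd: float
    amplitude: float
    r_squared: float
    mean_uncertainty: float
    sd_uncertainty: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")


@dataclass
class TTestResult:
    statistic: float
    p_value: float
    df: float
    variant: str


def mask_to_contact(film: FilmDoseMap, contact: FilmDoseMap) -> FilmDoseMap:
    """Restrict the film map to the contact region of the unfolded TPS map."""
    if not film.same_lattice(contact):
        raise LatticeMismatchError("film and contact maps must share the lattice")
    valid = film.valid_mask & contact.valid_mask
    if not valid.any():
        raise GeometryError("film and contact region do not overlap")
    dose = np.where(valid, film.dose, np.nan)
    return film.copy_with(dose=dose, valid_mask=valid)


def dose_difference(
    calculated: FilmDoseMap,
    measured: FilmDoseMap,
    regions: Optional[Dict[str, np.ndarray]] = None,
) -> DoseDifferenceMap:
    """Pixel-by-pixel calculated - measured difference on the common mask."""
    if not calculated.same_lattice(measured):
        raise LatticeMismatchError("maps must share the lattice")
    valid = calculated.valid_mask & measured.valid_mask
    diff = np.where(valid, calculated.dose - measured.dose, np.nan)
    return DoseDifferenceMap(diff, valid, calculated.pixel_spacing, regions)


def pooled_histogram(
    diffs: Sequence[DoseDifferenceMap],
    region: str = "full",
    bin_width: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Histogram of pooled pixel differences, bins centred on multiples of
    ``bin_width``. Returns (edges, counts)."""
    if len(diffs) == 0:
        raise ValueError("need at least one difference map")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    pool = np.concatenate([d.values(region) for d in diffs])
    if pool.size == 0:
        return np.array([-bin_width / 2, bin_width / 2]), np.zeros(1)
    lo = np.floor(pool.min() / bin_width) * bin_width - bin_width / 2
    hi = np.ceil(pool.max() / bin_width) * bin_width + bin_width / 2
    n = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n + 1)
    counts, _ = np.histogram(pool, bins=edges)
    return edges, counts.astype(float)


def fit_gaussian(edges: np.ndarray, counts: np.ndarray) -> GaussianFit:
    """Nonlinear least-squares Gaussian fit to histogram counts.

    Initialised from the histogram's weighted mean and SD. Reports R^2
    against the counts and the coefficient standard errors from the fit
    covariance.
    """
    edges = np.asarray(edges, dtype=float)
    counts = np.asarray(counts, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if np.count_nonzero(counts) < 5:
        raise FitError("need at least 5 non-empty bins for a Gaussian fit")
    total = counts.sum()
    mu0 = float((centers * counts).sum() / total)
    sd0 = float(np.sqrt(((centers - mu0) ** 2 * counts).sum() / total))
    sd0 = max(sd0, (edges[1] - edges[0]) / 2)
    a0 = float(counts.max())

    def model(x, a, mu, sd):
        return a * np.exp(-((x - mu) ** 2) / (2.0 * sd ** 2))

    try:
        popt, pcov = optimize.curve_fit(
            model, centers, counts, p0=[a0, mu0, sd0], maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError(
            f"Gaussian fit did not converge (init a={a0:.3g}, mu={mu0:.3g}, "
            f"sd={sd0:.3g}): {exc}"
        ) from exc
    a, mu, sd = popt
    sd = abs(float(sd))
    resid = counts - model(centers, *popt)
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((counts - counts.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(3, np.nan)
    return GaussianFit(float(mu), sd, float(a), float(np.clip(r2, 0.0, 1.0)),
                       float(perr[1]), float(perr[2]))


def fit_gaussian_or_moments(edges: np.ndarray, counts: np.ndarray) -> GaussianFit:
    """Gaussian fit with a moment-based fallback for degenerate histograms.

    Near-delta histograms (e.g. noise-free synthetic runs concentrating all
    mass in fewer than five bins) cannot support a nonlinear fit; the
    weighted mean/SD of the histogram are reported instead, with R^2 = 1 and
    undefined coefficient uncertainties.
    """
    try:
        return fit_gaussian(edges, counts)
    except FitError:
        counts = np.asarray(counts, dtype=float)
        centers = 0.5 * (np.asarray(edges[:-1]) + np.asarray(edges[1:]))
        total = counts.sum()
        if total <= 0:
            raise
        mu = float((centers * counts).sum() / total)
        sd = float(np.sqrt(((centers - mu) ** 2 * counts).sum() / total))
        sd = max(sd, float(edges[1] - edges[0]) / np.sqrt(12.0))
        return GaussianFit(mu, sd, float(counts.max()), 1.0, float("nan"),
                           float("nan"))


def compare_algorithms(
    diffs_a: Sequence[np.ndarray],
    diffs_b: Sequence[np.ndarray],
    variant: str = "per_case_paired",
) -> TTestResult:
    """t-test between two algorithms' difference distributions.

    ``pooled_welch`` runs Welch's two-sample t on all pooled pixels (the
    literal pixel-pool comparison; spatial autocorrelation inflates n).
    ``per_case_paired`` runs a paired t on per-case mean differences
    (conservative; requires matched cases).
    """
    a_list = [np.asarray(a, dtype=float).ravel() for a in diffs_a]
    b_list = [np.asarray(b, dtype=float).ravel() for b in diffs_b]
    if not a_list or not b_list:
        raise ValueError("both pools must be non-empty")
    if variant == "pooled_welch":
        a = np.concatenate(a_list)
        b = np.concatenate(b_list)
        res = stats.ttest_ind(a, b, equal_var=False)
        na, nb = a.size, b.size
        va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
        df = (va + vb) ** 2 / (va ** 2 / (na - 1) + vb ** 2 / (nb - 1))
        return TTestResult(float(res.statistic), float(res.pvalue), float(df),
                           variant)
    if variant == "per_case_paired":
        if len(a_list) != len(b_list):
            raise ValueError("per_case_paired requires matched case lists")
        ma = np.array([a.mean() for a in a_list])
        mb = np.array([b.mean() for b in b_list])
        if len(ma) < 2:
            raise ValueError("per_case_paired requires at least two cases")
        res = stats.ttest_rel(ma, mb)
        return TTestResult(float(res.statistic), float(res.pvalue),
                           float(len(ma) - 1), variant)
    raise ValueError(f"unknown t-test variant {variant!r}")
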