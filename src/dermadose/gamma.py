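"""Gamma-index comparison of 2D dose maps.

For each valid reference pixel r the gamma index is

    gamma(r) = min_e sqrt( |e - r|^2 / DTA^2 + (D_eval(e) - D_ref(r))^2 / tol^2 )

over evaluated positions e within ``search_radius_factor * DTA`` of r, with
the evaluated map upsampled by bilinear interpolation to control
discretisation error. Doses are percent of prescription and the tolerance is
global (relative to prescription). gamma <= 1 counts as agreement.

The search enumerates candidate offsets in order of increasing distance and
stops as soon as the pure distance term exceeds every pixel's current best
gamma — an exact early termination, so the result equals the exhaustive
minimisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import FilmDoseMap, LatticeMismatchError


@dataclass
class GammaCriteria:
    """Acceptance criteria for the gamma comparison."""

    dta: float = 0.5                 # distance to agreement, cm
    dose_tol: float = 7.0            # dose tolerance, % of prescription
    normalization: str = "global"
    low_dose_threshold: float = 0.0  # % of prescription; 0 disables
    search_radius_factor: float = 3.0
    upsample: int = 3

    def __post_init__(self) -> None:
        if self.dta <= 0 or self.dose_tol <= 0:
            raise ValueError("dta and dose_tol must be positive")
        if self.normalization != "global":
            raise NotImplementedError(
                "only global normalization is implemented"
            )
        if self.upsample < 1:
            raise ValueError("upsample must be >= 1")

    @property
    def label(self) -> str:
        return f"{self.dose_tol:g}%/{self.dta:g}cm"


@dataclass
class GammaMap:
    """Per-pixel gamma values and the pass rate over evaluated pixels."""

    gamma: np.ndarray
    criteria: GammaCriteria
    pixel_spacing: float

    @property
    def evaluated_mask(self) -> np.ndarray:
        return np.isfinite(self.gamma)

    @property
    def pass_rate(self) -> float:
        return self.pass_rate_in(None)

    def pass_rate_in(self, region: Optional[np.ndarray]) -> float:
        """Percent of evaluated pixels with gamma <= 1 inside a region."""
        mask = self.evaluated_mask
        if region is not None:
            mask = mask & region
        n = int(mask.sum())
        if n == 0:
            return float("nan")
        return 100.0 * float((self.gamma[mask] <= 1.0).sum()) / n


def _upsample_fine(dose: np.ndarray, valid: np.ndarray, k: int) -> np.ndarray:
    """Bilinear upsample with NaN outside the valid mask.

    Fine sample (i, j) sits at coarse position (i/k, j/k); samples whose
    interpolation stencil touches an invalid pixel become NaN.
    """
    work = np.where(valid, dose, np.nan)
    if k == 1:
        return work.copy()
    h, w = dose.shape
    fi = np.arange((h - 1) * k + 1) / k
    fj = np.arange((w - 1) * k + 1) / k
    rr, cc = np.meshgrid(fi, fj, indexing="ij")
    fine = ndimage.map_coordinates(work, np.stack([rr, cc]), order=1,
                                   mode="constant", cval=np.nan)
    # samples coincident with coarse pixels take the exact pixel value
    # (zero-weight NaN neighbours must not invalidate them)
    fine[::k, ::k] = work
    return fine


def gamma_index_multi(
    reference: FilmDoseMap,
    evaluated: FilmDoseMap,
    criteria_list: Sequence[GammaCriteria],
) -> List[GammaMap]:
    """Gamma maps for several criteria sharing one candidate sweep.

    All criteria must share DTA, search radius and upsampling so the
    candidate set is common; dose tolerances may differ (the usual 7% vs 10%
    pairing).
    """
    if not criteria_list:
        raise ValueError("need at least one criteria set")
    if not reference.same_lattice(evaluated):
        raise LatticeMismatchError(
            "reference and evaluated maps must share the lattice"
        )
    c0 = criteria_list[0]
    for c in criteria_list[1:]:
        if (c.dta, c.search_radius_factor, c.upsample) != (
            c0.dta, c0.search_radius_factor, c0.upsample
        ):
            raise ValueError(
                "criteria in one sweep must share dta/search radius/upsample"
            )
    sp = reference.pixel_spacing
    k = c0.upsample
    sf = sp / k
    radius = c0.search_radius_factor * c0.dta
    pad = int(np.ceil(radius / sf))

    fine = _upsample_fine(evaluated.dose, evaluated.valid_mask, k)
    fine_p = np.pad(fine, pad, mode="constant", constant_values=np.nan)

    h, w = reference.shape
    ref = np.where(reference.valid_mask, reference.dose, np.nan)

    # candidate offsets sorted by physical distance
    span = np.arange(-pad, pad + 1)
    di, dj = np.meshgrid(span, span, indexing="ij")
    dist = sf * np.hypot(di, dj)
    inside = dist <= radius + 1e-12
    order = np.argsort(dist[inside], kind="stable")
    offs = np.column_stack([di[inside][order], dj[inside][order]])
    dists = dist[inside][order]

    tols = [c.dose_tol for c in criteria_list]
    gamma2 = [np.full((h, w), np.inf) for _ in criteria_list]
    row0 = col0 = pad
    running_max = np.inf
    for n, ((oi, oj), d) in enumerate(zip(offs, dists)):
        d2 = (d / c0.dta) ** 2
        if d2 >= running_max:
            break
        shifted = fine_p[
            row0 + oi: row0 + oi + (h - 1) * k + 1: k,
            col0 + oj: col0 + oj + (w - 1) * k + 1: k,
        ]
        delta = shifted - ref
        for g2, tol in zip(gamma2, tols):
            cand = d2 + (delta / tol) ** 2
            np.fmin(g2, cand, out=g2, where=np.isfinite(cand))
        if n % 16 == 15:
            running_max = 0.0
            for g2 in gamma2:
                vals = g2[np.isfinite(ref)]
                if vals.size:
                    running_max = max(running_max, float(vals.max()))
            if not np.isfinite(running_max):
                running_max = np.inf

    out = []
    for g2, crit in zip(gamma2, criteria_list):
        g = np.sqrt(g2)
        g[~np.isfinite(ref)] = np.nan       # undefined outside reference mask
        g[~np.isfinite(g)] = np.nan         # fully-invalid neighbourhoods
        if crit.low_dose_threshold > 0:
            g[np.where(np.isfinite(ref) & (ref < crit.low_dose_threshold))] = np.nan
        out.append(GammaMap(g, crit, sp))
    return out


def gamma_index(
    reference: FilmDoseMap,
    evaluated: FilmDoseMap,
    criteria: GammaCriteria,
) -> GammaMap:
    """Gamma map of an evaluated dose map against a reference map."""
    return gamma_index_multi(reference, evaluated, [criteria])[0]


def gamma_report(
    pass_rates: Dict[str, Dict[str, Dict[str, List[float]]]]
) -> pd.DataFrame:
    """Mean +/- SD gamma passing rates per criteria x algorithm x region.

    ``pass_rates[criteria_label][algorithm][region]`` is the list of
    per-case pass rates. Returns a table with (criteria, stat) rows and
    (algorithm, region) columns — the gamma-summary table shape.
    """
    rows = []
    row_index = []
    columns = None
    for crit_label, algos in pass_rates.items():
        cols, means, sds = [], [], []
        for algo, regions in algos.items():
            for region, vals in regions.items():
                arr = np.asarray(vals, dtype=float)
                cols.append((algo, region))
                means.append(np.nanmean(arr))
                sds.append(np.nanstd(arr, ddof=1) if arr.size > 1 else 0.0)
        columns = pd.MultiIndex.from_tuples(cols, names=["algorithm", "region"])
        rows.extend([means, sds])
        row_index.extend([(crit_label, "mean"), (crit_label, "sd")])
    if columns is None:
        raise ValueError("no pass rates supplied")
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(row_index, names=["criteria", "stat"]),
        columns=columns,
    )
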