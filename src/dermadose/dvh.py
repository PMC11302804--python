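"""Cumulative dose-volume histograms and Dx% extraction.

Doses are expressed as percent of prescription, voxels are equally weighted
(no partial-volume subdivision) and sampled trilinearly at voxel centres when
the dose lattice differs from the structure lattice. ``Dx%`` follows the
hottest-volume convention: the minimum dose received by the hottest x% of
the structure volume, read off the binned cumulative curve with linear
interpolation on strictly decreasing segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .core import DoseGrid, GeometryError, StructureMask


@dataclass
class DVHCurve:
    """Cumulative DVH: volume fraction receiving at least each dose edge.

    ``cumulative_above`` (fraction receiving strictly more than each edge)
    distinguishes point masses sitting exactly on an edge from continuous
    mass inside the following bin, which keeps uniform-dose Dx% queries
    exact.
    """

    dose_edges: np.ndarray          # percent of prescription, uniform bins
    cumulative_volume_fraction: np.ndarray
    voxel_count: int
    structure_label: str = ""
    bin_width: float = 0.5
    cumulative_above: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dose_edges = np.asarray(self.dose_edges, dtype=float)
        self.cumulative_volume_fraction = np.asarray(
            self.cumulative_volume_fraction, dtype=float
        )
        if self.dose_edges.shape != self.cumulative_volume_fraction.shape:
            raise ValueError("edges and fractions must align")
        if self.cumulative_above is not None:
            self.cumulative_above = np.asarray(self.cumulative_above, dtype=float)


def dvh_from_doses(doses_pct: np.ndarray, bin_width: float = 0.5,
                   label: str = "") -> DVHCurve:
    """Cumulative DVH of a flat array of per-voxel doses (percent)."""
    doses = np.asarray(doses_pct, dtype=float).ravel()
    if doses.size == 0:
        raise GeometryError("empty structure: no doses to histogram")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    top = float(doses.max())
    n_bins = int(np.floor(top / bin_width)) + 2
    edges = bin_width * np.arange(n_bins + 1)
    srt = np.sort(doses)
    # fraction of voxels with dose >= edge (inclusive) and > edge (strict)
    frac = 1.0 - np.searchsorted(srt, edges, side="left") / doses.size
    above = 1.0 - np.searchsorted(srt, edges, side="right") / doses.size
    return DVHCurve(edges, frac, int(doses.size), label, bin_width, above)


def compute_dvh(dose: DoseGrid, mask: StructureMask,
                bin_width: float = 0.5) -> DVHCurve:
    """Cumulative DVH over trilinear voxel-centre doses of a structure."""
    if not mask.mask.any():
        raise GeometryError("empty structure mask")
    pts = mask.voxel_centers()
    doses = dose.sample_percent(pts)
    return dvh_from_doses(doses, bin_width, mask.label)


def dose_at_volume(curve: DVHCurve, volume_pct: float) -> float:
    """Dx%: minimum dose received by the hottest ``volume_pct`` of the volume.

    The largest dose at which the cumulative curve still reaches
    ``volume_pct / 100``, with linear interpolation between bin edges where
    the curve strictly decreases.
    """
    if not 0 < volume_pct <= 100:
        raise ValueError("volume_pct must be in (0, 100]")
    target = volume_pct / 100.0
    frac = curve.cumulative_volume_fraction
    edges = curve.dose_edges
    at_least = np.nonzero(frac >= target)[0]
    if at_least.size == 0:
        return float(edges[0])
    i = int(at_least[-1])
    if i == len(edges) - 1 or frac[i] == target:
        return float(edges[i])
    if curve.cumulative_above is not None and curve.cumulative_above[i] < target:
        # the curve steps through the target exactly at this edge
        return float(edges[i])
    # curve drops below target between edges i and i+1
    f0, f1 = frac[i], frac[i + 1]
    if f1 >= f0:
        return float(edges[i])
    t = (f0 - target) / (f0 - f1)
    return float(edges[i] + t * (edges[i + 1] - edges[i]))


def summarize_structures(
    d50_by_case: Dict[str, Dict[str, Sequence[float]]]
) -> pd.DataFrame:
    """Mean +/- SD of D50% across cases, per algorithm x structure.

    ``d50_by_case[algorithm][structure]`` is the list of per-case D50%
    values. All cells must hold the same number of cases. The result has
    rows ``mean`` and ``sd`` and a (algorithm, structure) column MultiIndex —
    the D50% summary-table shape.
    """
    if not d50_by_case:
        raise ValueError("no cases supplied")
    lengths = {
        len(vals)
        for structs in d50_by_case.values()
        for vals in structs.values()
    }
    if len(lengths) != 1:
        raise ValueError(f"inconsistent case counts across cells: {lengths}")
    (n_cases,) = lengths
    if n_cases < 1:
        raise ValueError("need at least one case")
    cols, means, sds = [], [], []
    for algo, structs in d50_by_case.items():
        for struct, vals in structs.items():
            arr = np.asarray(list(vals), dtype=float)
            cols.append((algo, struct))
            means.append(arr.mean())
            sds.append(arr.std(ddof=1) if n_cases > 1 else 0.0)
    index = pd.MultiIndex.from_tuples(cols, names=["algorithm", "structure"])
    return pd.DataFrame([means, sds], index=["mean", "sd"], columns=index)


def format_mean_sd(table: pd.DataFrame, decimals: int = 0) -> pd.DataFrame:
    """Render a mean/sd table as ``mean ± sd`` percent strings."""
    out = {}
    for col in table.columns:
        m, s = table.loc["mean", col], table.loc["sd", col]
        out[col] = f"{m:.{decimals}f} ± {s:.{decimals}f}%"
    return pd.DataFrame([out], index=["Mean ± SD"])
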