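"""End-to-end orchestration: synthetic cohort -> structures -> DVH ->
film processing -> registration -> dose-difference/gamma statistics ->
report bundle.

The default synthetic cohort has 18 cases with per-case randomised breast
size, prescription (42.5 Gy/16 fx or 50 Gy/25 fx) and film noise; most cases
use a 0.1 cm dose lattice and the final sixth 0.15 cm, echoing clinical
calculation-grid practice. Every report cell is recomputable from persisted
per-case artifacts.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .compare import (
    DoseDifferenceMap,
    GaussianFit,
    TTestResult,
    compare_algorithms,
    dose_difference,
    fit_gaussian_or_moments,
    mask_to_contact,
    pooled_histogram,
)
from .core import ConfigError, DoseGrid, FilmDoseMap, StructureMask
from .dvh import compute_dvh, dose_at_volume, summarize_structures
from .film import (
    average_fractions,
    denoise,
    register_rigid,
    resample_rigid,
    resample_spacing,
    trim_edges,
)
from .gamma import GammaCriteria, gamma_index_multi, gamma_report
from .structures import contact_surface, make_rind, threshold_structure
from .synthetic import (
    AlgorithmProfile,
    FilmNoiseModel,
    PhantomSpec,
    compute_dose_geometry,
    default_profiles,
    generate_dose_grid,
    generate_film_measurement,
    generate_phantom_ct,
)
from .unfold import (
    FILM_SPACING,
    extract_surface_dose,
    rasterize_to_film_grid,
    segment_lat_inf,
    unfold_surface,
)

REGIONS = ("full", "lateral", "inferior")


@dataclass
class RunConfig:
    """Configuration of a full synthetic (or real-data) analysis run."""

    mode: str = "synthetic"
    n_cases: int = 18
    seed: int = 0
    phantom: Dict = field(default_factory=dict)
    randomize_phantom: bool = True
    truth_profile: str = "truth"
    algorithms: Tuple[str, ...] = ("aaa_like", "axb_like")
    profile_overrides: Dict[str, Dict] = field(default_factory=dict)
    noise: Dict = field(default_factory=lambda: {
        "systematic_offset": 0.0,
        "noise_sd": 7.5,
        "ridge_amplitude": 2.0,
        "ridge_period": 1.2,
        "max_shift_cm": 0.08,
        "max_rotation_deg": 0.5,
    })
    n_fractions: int = 3
    rind_thicknesses: Tuple[float, ...] = (0.2, 0.5)
    gamma_criteria: Tuple[Tuple[float, float], ...] = ((0.5, 7.0), (0.5, 10.0))
    gamma_spacing: float = 0.1
    film_spacing: float = FILM_SPACING
    dvh_bin_width: float = 0.5
    body_hu_range: Tuple[float, float] = (-300.0, 3071.0)
    cradle_hu_range: Tuple[float, float] = (-800.0, -600.0)
    ttest_variant: str = "per_case_paired"
    stages: Tuple[str, ...] = ("dvh", "film", "gamma")
    reg_max_rotation: float = 4.0
    reg_coarse_angles: int = 9
    outdir: Optional[str] = None

    @classmethod
    def from_dict(cls, d: Dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> Dict:
        d = asdict(self)
        for key in ("algorithms", "rind_thicknesses", "stages"):
            d[key] = list(d[key])
        d["gamma_criteria"] = [list(c) for c in self.gamma_criteria]
        d["body_hu_range"] = list(self.body_hu_range)
        d["cradle_hu_range"] = list(self.cradle_hu_range)
        return d


def validate_config(config: RunConfig) -> List[Tuple[str, str]]:
    """Static checks; returns (severity, message) findings."""
    findings: List[Tuple[str, str]] = []
    if config.mode not in ("synthetic", "real"):
        findings.append(("error", f"unknown mode {config.mode!r}"))
    if config.n_cases < 1:
        findings.append(("error", "n_cases must be >= 1"))
    if any(t < 0 for t in config.rind_thicknesses):
        findings.append(("error", "rind thicknesses must be non-negative"))
    for dta, tol in config.gamma_criteria:
        if dta <= 0 or tol <= 0:
            findings.append(("error", f"invalid gamma criteria ({dta}, {tol})"))
    lo, hi = config.body_hu_range
    if lo > hi:
        findings.append(("error", "body HU range is inverted"))
    elif hi <= -900:
        findings.append((
            "warning",
            "body HU band spans only air; bands quoted as '-1000 to -3071' "
            "are a known description erratum — use a tissue band such as "
            "[-300, 3071]",
        ))
    if config.n_fractions < 1:
        findings.append(("error", "n_fractions must be >= 1"))
    if config.mode == "synthetic":
        try:
            PhantomSpec(**config.phantom)
        except (TypeError, ValueError) as exc:
            findings.append(("error", f"invalid phantom spec: {exc}"))
    return findings


@dataclass
class CaseResult:
    """All per-case artifacts a report cell can be traced back to."""

    case_id: int
    spec: PhantomSpec
    d50: Dict[str, Dict[str, float]]                 # algorithm -> structure -> D50%
    diffs: Dict[str, DoseDifferenceMap]              # algorithm -> diff map
    gamma_pass: Dict[str, Dict[str, Dict[str, float]]]
    measured: Optional[FilmDoseMap] = None
    calc_maps: Dict[str, FilmDoseMap] = field(default_factory=dict)


@dataclass
class ReportBundle:
    """Cohort-level report mirroring the summary-table shapes."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: Optional[pd.DataFrame]
    fits: Dict[str, Dict[str, GaussianFit]]
    histograms: Dict[str, Dict[str, Tuple[np.ndarray, np.ndarray]]]
    ttests: Dict[str, TTestResult]
    cases: List[CaseResult]
    log: Dict

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table1.to_csv(outdir / "table1_d50.csv", float_format="%.6f")
        self.table2.to_csv(outdir / "table2_rind_shifts.csv",
                           float_format="%.6f")
        if self.table3 is not None:
            self.table3.to_csv(outdir / "table3_gamma.csv",
                               float_format="%.6f")
        rows = []
        for algo, by_region in self.fits.items():
            for region, fit in by_region.items():
                rows.append({
                    "algorithm": algo, "region": region, "mean": fit.mean,
                    "sd": fit.sd, "amplitude": fit.amplitude,
                    "r_squared": fit.r_squared,
                    "mean_uncertainty": fit.mean_uncertainty,
                })
        pd.DataFrame(rows).to_csv(outdir / "gaussian_fits.csv", index=False,
                                  float_format="%.6f")
        with open(outdir / "run_log.txt", "w") as fh:
            for k, v in self.log.items():
                fh.write(f"{k}: {v}\n")


def _case_spec(config: RunConfig, rng: np.random.Generator,
               case_id: int) -> PhantomSpec:
    base = dict(config.phantom)
    if config.randomize_phantom:
        base.setdefault("breast_radius", float(rng.uniform(3.4, 4.6)))
        base.setdefault("prescription", float(rng.choice([42.5, 50.0])))
    # most cases on the fine calculation lattice, the last sixth on 0.15 cm
    if "dose_grid_spacing" not in base:
        coarse_from = config.n_cases - max(config.n_cases // 6, 0)
        base["dose_grid_spacing"] = 0.15 if case_id >= coarse_from else 0.1
    return PhantomSpec(**base)


def _profiles(config: RunConfig) -> Dict[str, AlgorithmProfile]:
    profiles = default_profiles()
    for name, overrides in config.profile_overrides.items():
        base = profiles.get(name)
        kwargs = dict(
            name=name,
            **{k: getattr(base, k) for k in (
                "surface_dose_fraction", "buildup_length", "surface_bias",
                "lateral_scatter_deficit", "global_bias")}
        ) if base is not None else {"name": name}
        kwargs.update(overrides)
        profiles[name] = AlgorithmProfile(**kwargs)
    return profiles


def run_case(config: RunConfig, case_id: int,
             rng: np.random.Generator) -> CaseResult:
    """Run all configured stages for one synthetic case."""
    spec = _case_spec(config, rng, case_id)
    profiles = _profiles(config)
    ct, _ = generate_phantom_ct(spec)
    body = threshold_structure(ct, *config.body_hu_range, keep_largest=True,
                               label="body")
    cradle = threshold_structure(ct, *config.cradle_hu_range, label="cradle")
    contact = contact_surface(body, cradle)
    structures: Dict[str, StructureMask] = {"surface": contact}
    for t in config.rind_thicknesses:
        structures[f"rind_{t:g}cm"] = make_rind(contact, body, t)

    geometry = compute_dose_geometry(spec)
    truth_dose = generate_dose_grid(spec, profiles[config.truth_profile],
                                    geometry)
    algo_doses = {
        name: generate_dose_grid(spec, profiles[name], geometry)
        for name in config.algorithms
    }

    d50: Dict[str, Dict[str, float]] = {}
    if "dvh" in config.stages:
        for name, dg in algo_doses.items():
            d50[name] = {}
            for sname, smask in structures.items():
                curve = compute_dvh(dg, smask, config.dvh_bin_width)
                d50[name][sname] = dose_at_volume(curve, 50.0)

    diffs: Dict[str, DoseDifferenceMap] = {}
    gamma_pass: Dict[str, Dict[str, Dict[str, float]]] = {}
    measured = None
    calc_maps: Dict[str, FilmDoseMap] = {}
    if "film" in config.stages or "gamma" in config.stages:
        truth_sample = extract_surface_dose(truth_dose, contact)
        truth_map = rasterize_to_film_grid(
            unfold_surface(truth_sample), config.film_spacing, "truth_surface"
        )
        for name, dg in algo_doses.items():
            sample = extract_surface_dose(dg, contact)
            calc_maps[name] = rasterize_to_film_grid(
                unfold_surface(sample), config.film_spacing,
                f"unfolded_{name}"
            )

        noise = FilmNoiseModel(**config.noise)
        fractions = generate_film_measurement(
            truth_map, noise, config.n_fractions, rng=rng
        )
        processed = [denoise(trim_edges(f, 2)) for f in fractions]
        registered = [processed[0]]
        for frac in processed[1:]:
            _, resampled = register_rigid(
                frac, processed[0],
                max_rotation_deg=config.reg_max_rotation,
                coarse_angles=config.reg_coarse_angles,
            )
            registered.append(resampled)
        measured = average_fractions(registered)

        # register the mean measured map onto the unfolded TPS lattice; the
        # transform is estimated once against the first algorithm's map
        first = config.algorithms[0]
        transform, film_on_tps = register_rigid(
            measured, calc_maps[first],
            max_rotation_deg=config.reg_max_rotation,
            coarse_angles=config.reg_coarse_angles,
        )
        for name in config.algorithms:
            calc = calc_maps[name]
            film_masked = mask_to_contact(film_on_tps, calc)
            regions = segment_lat_inf(
                calc, spec.lateral_extent, spec.inferior_extent
            )
            diffs[name] = dose_difference(calc, film_masked, regions)

        if "gamma" in config.stages:
            criteria = [
                GammaCriteria(dta=d, dose_tol=t)
                for d, t in config.gamma_criteria
            ]
            film_g = resample_spacing(film_on_tps, config.gamma_spacing)
            region_g = segment_lat_inf(film_g, spec.lateral_extent,
                                       spec.inferior_extent)
            for name in config.algorithms:
                calc_g = resample_spacing(calc_maps[name],
                                          config.gamma_spacing)
                maps = gamma_index_multi(film_g, calc_g, criteria)
                gamma_pass[name] = {}
                for crit, gmap in zip(criteria, maps):
                    gamma_pass[name][crit.label] = {
                        r: gmap.pass_rate_in(region_g[r]) for r in REGIONS
                    }

    return CaseResult(case_id, spec, d50, diffs, gamma_pass, measured,
                      calc_maps)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the configured cohort and assemble the report bundle."""
    findings = validate_config(config)
    errors = [msg for sev, msg in findings if sev == "error"]
    if errors:
        raise ConfigError("; ".join(errors))
    if config.mode != "synthetic":
        raise NotImplementedError(
            "real-data orchestration: load DICOM/TIFF inputs with dermadose.io "
            "and drive the module functions directly"
        )

    children = np.random.SeedSequence(config.seed).spawn(config.n_cases)
    cases: List[CaseResult] = []
    for cid in range(config.n_cases):
        rng = np.random.default_rng(children[cid])
        try:
            cases.append(run_case(config, cid, rng))
        except Exception as exc:
            raise RuntimeError(f"stage failure in case {cid}: {exc}") from exc

    # ---- Table 1: D50% mean +/- SD per algorithm x structure -------------
    table1 = None
    d50_by = {}
    if "dvh" in config.stages:
        struct_names = list(cases[0].d50[config.algorithms[0]].keys())
        d50_by = {
            algo: {s: [c.d50[algo][s] for c in cases] for s in struct_names}
            for algo in config.algorithms
        }
        table1 = summarize_structures(d50_by)

    # ---- pooled histograms, Gaussian fits, t-tests -----------------------
    fits: Dict[str, Dict[str, GaussianFit]] = {}
    hists: Dict[str, Dict[str, Tuple[np.ndarray, np.ndarray]]] = {}
    ttests: Dict[str, TTestResult] = {}
    if "film" in config.stages and cases[0].diffs:
        for algo in config.algorithms:
            fits[algo], hists[algo] = {}, {}
            for region in REGIONS:
                edges, counts = pooled_histogram(
                    [c.diffs[algo] for c in cases], region
                )
                hists[algo][region] = (edges, counts)
                fits[algo][region] = fit_gaussian_or_moments(edges, counts)
        if len(config.algorithms) >= 2 and len(cases) >= 2:
            a, b = config.algorithms[:2]
            for region in REGIONS:
                ttests[region] = compare_algorithms(
                    [c.diffs[a].values(region) for c in cases],
                    [c.diffs[b].values(region) for c in cases],
                    config.ttest_variant,
                )

    # ---- Table 2: rind dose increases and calc-minus-measured shifts -----
    table2 = None
    if table1 is not None and fits:
        struct_names = list(cases[0].d50[config.algorithms[0]].keys())
        rows = {}
        increase = {}
        for algo in config.algorithms:
            for s in struct_names:
                shift = (table1.loc["mean", (algo, s)]
                         - table1.loc["mean", (algo, "surface")])
                increase[(algo, s)] = shift
        rows["tps_dose_increase"] = increase
        for region in REGIONS:
            rows[f"calc_minus_measured_{region}"] = {
                (algo, s): fits[algo][region].mean + increase[(algo, s)]
                for algo in config.algorithms for s in struct_names
            }
        table2 = pd.DataFrame(rows).T
        table2.columns = pd.MultiIndex.from_tuples(
            table2.columns, names=["algorithm", "structure"]
        )

    # ---- Table 3: gamma pass rates ---------------------------------------
    table3 = None
    if "gamma" in config.stages and cases[0].gamma_pass:
        crit_labels = list(next(iter(cases[0].gamma_pass.values())).keys())
        nested = {
            lbl: {
                algo: {
                    r: [c.gamma_pass[algo][lbl][r] for c in cases]
                    for r in REGIONS
                }
                for algo in config.algorithms
            }
            for lbl in crit_labels
        }
        table3 = gamma_report(nested)

    cfg_yaml = __import__("yaml").safe_dump(config.to_dict(), sort_keys=True)
    log = {
        "dermadose_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "n_cases": config.n_cases,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "stages": ",".join(config.stages),
    }
    if table1 is None:
        table1 = pd.DataFrame()
    if table2 is None:
        table2 = pd.DataFrame()
    bundle = ReportBundle(table1, table2, table3, fits, hists, ttests, cases,
                          log)
    if config.outdir:
        bundle.save(config.outdir)
        _save_cases(config, bundle)
        if fits:
            plot_histograms(bundle, Path(config.outdir) / "figure_histograms.png")
    return bundle


def _save_cases(config: RunConfig, bundle: ReportBundle) -> None:
    from .io import write_film_csv

    outdir = Path(config.outdir)
    for case in bundle.cases:
        cdir = outdir / f"case_{case.case_id:02d}"
        cdir.mkdir(parents=True, exist_ok=True)
        if case.d50:
            pd.DataFrame(case.d50).to_csv(cdir / "d50.csv",
                                          float_format="%.6f")
        if case.measured is not None:
            write_film_csv(case.measured, cdir / "mean_measured.csv")
        for name, cmap in case.calc_maps.items():
            write_film_csv(cmap, cdir / f"calc_{name}.csv")
        if case.gamma_pass:
            rows = [
                {"algorithm": a, "criteria": lbl, "region": r, "pass_rate": v}
                for a, by_lbl in case.gamma_pass.items()
                for lbl, by_r in by_lbl.items()
                for r, v in by_r.items()
            ]
            pd.DataFrame(rows).to_csv(cdir / "gamma_pass.csv", index=False,
                                      float_format="%.6f")


def plot_histograms(bundle: ReportBundle, path) -> None:
    """Panel plot of pooled dose-difference histograms with Gaussian fits."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    algos = list(bundle.histograms.keys())
    fig, axes = plt.subplots(len(algos), len(REGIONS),
                             figsize=(4 * len(REGIONS), 3 * len(algos)),
                             squeeze=False)
    for i, algo in enumerate(algos):
        for j, region in enumerate(REGIONS):
            ax = axes[i][j]
            edges, counts = bundle.histograms[algo][region]
            centers = 0.5 * (edges[:-1] + edges[1:])
            ax.bar(centers, counts, width=edges[1] - edges[0],
                   color="steelblue", alpha=0.7)
            fit = bundle.fits[algo][region]
            xs = np.linspace(edges[0], edges[-1], 300)
            ax.plot(xs, fit.amplitude
                    * np.exp(-((xs - fit.mean) ** 2) / (2 * fit.sd ** 2)),
                    "r-")
            ax.set_title(f"{algo} {region}: "
                         f"{fit.mean:.1f} ± {fit.sd:.1f}%")
            ax.set_xlabel("calc − measured (% of prescription)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
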