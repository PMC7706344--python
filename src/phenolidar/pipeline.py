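"""End-to-end runs: simulate → extract → growth rate → repeatability.

A run is fully described by a :class:`RunConfig` (serializable, hashable);
given the same config and seed, a run is deterministic down to the bytes of
its JSON report. Scanning events are placed between the earliest GS31 and
the latest GS65 in the simulated trial, so every plot's growth window is
bracketed by data and no extrapolation is ever needed.

Residual normality (Shapiro–Wilk) and variance homogeneity (ratio of the
residual variances of the two halves of the fitted-value range) are
computed per event × trait as advisory diagnostics: they are logged and
reported, never gating.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .design import TrialDesign, simulate_design, write_design
from .errors import PhenolidarError, ValidationError
from .growth import cgr_table
from .indices import compute_3dpi, compute_3dvi
from .pointcloud import crop_height, estimate_ground
from .simulate import (
    ScanConfig,
    SimTruth,
    TruthSpec,
    simulate_agb,
    simulate_ndvi,
    simulate_scan,
    simulate_truth,
)
from .varcomp import correlate_blups, fit_random_effects

__all__ = ["RunConfig", "run_event_analysis", "run_cgr_analysis", "run_all", "extract_traits"]

log = logging.getLogger(__name__)

LIDAR_TRAITS = ("height", "3dvi", "3dpi")


@dataclass(frozen=True)
class RunConfig:
    """Complete, validated parameter set of one reproducible run."""

    scenario: str = "well_watered"
    seed: int = 0
    n_genotypes: int = 20
    design_type: str = "rcbd"
    replication: tuple = (3,)  # rcbd: (n_reps,); partial_rep: (n_plots, lo, hi)
    field_shape: tuple[int, int] | None = None
    n_events: int = 4
    quadrat_area: float = 0.3  # m²
    voxel_size: float = 0.05  # m
    layer: float = 0.01  # m
    dpi_variant: str = "interception"
    ground_bin: float = 0.01  # m
    include_trend: bool = False
    nrep_method: str = "arithmetic"
    traits: tuple[str, ...] = ("agb", "3dvi", "3dpi", "height", "ndvi")
    scan: dict = field(default_factory=dict)  # ScanConfig overrides
    truth: dict = field(default_factory=dict)  # TruthSpec overrides

    def __post_init__(self):
        if self.n_events < 2:
            raise ValidationError("need at least 2 events to bracket a growth window")
        if self.quadrat_area <= 0:
            raise ValidationError("quadrat_area must be > 0")
        ScanConfig(**self.scan)  # validate overrides eagerly
        TruthSpec(**self.truth)

    def scan_config(self) -> ScanConfig:
        return ScanConfig(**self.scan)

    def truth_spec(self) -> TruthSpec:
        return TruthSpec(**self.truth)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["replication"] = list(self.replication)
        d["traits"] = list(self.traits)
        d["field_shape"] = list(self.field_shape) if self.field_shape else None
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("replication", "traits", "field_shape"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _seeds(config: RunConfig, n: int) -> list[int]:
    ss = np.random.SeedSequence(config.seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _event_dates(truth: SimTruth, n_events: int) -> list[dt.date]:
    start = min(truth.gs31)
    end = max(truth.gs65)
    days = np.linspace(0, (end - start).days, n_events).round().astype(int)
    return [start + dt.timedelta(days=int(d)) for d in days]


def extract_traits(
    clouds: dict, design: TrialDesign, config: RunConfig, date
) -> pd.DataFrame:
    """Plot-level height, 3DVI and 3DPI from per-plot clouds of one event.

    The ground elevation is estimated per column of plots, pooling that
    column's clouds, as soil returns dominate the pooled height mode.
    """
    by_col: dict[int, list] = {}
    plot_col = {}
    for p in design.plots:
        by_col.setdefault(p.col, []).append(clouds[p.plot_id])
        plot_col[p.plot_id] = p.col
    grounds = {
        col: estimate_ground(cl, bin_width=config.ground_bin)
        for col, cl in by_col.items()
    }
    date_d = pd.Timestamp(date).date()
    rows = []
    for p in design.plots:
        cloud = clouds[p.plot_id]
        ground = grounds[plot_col[p.plot_id]]
        values = {
            "height": crop_height(cloud, ground),
            "3dvi": compute_3dvi(cloud, p.rect, ground, config.voxel_size),
            "3dpi": compute_3dpi(
                cloud, ground, config.layer, config.dpi_variant
            ),
        }
        for trait, value in values.items():
            rows.append(
                {
                    "plot_id": p.plot_id,
                    "genotype": p.genotype,
                    "row": p.row,
                    "col": p.col,
                    "date": date_d,
                    "trait": trait,
                    "value": float(value),
                }
            )
    return pd.DataFrame(rows)


def _simulate_and_extract(config: RunConfig, keep_clouds: bool = False):
    """Shared front half of every run: design, truth, per-event trait table."""
    seeds = _seeds(config, 4)
    replication = (
        int(config.replication[0])
        if config.design_type == "rcbd"
        else tuple(config.replication)
    )
    design = simulate_design(
        config.n_genotypes,
        config.design_type,
        replication,
        config.field_shape,
        rng_seed=seeds[0],
    )
    truth = simulate_truth(
        design, config.truth_spec(), config.scenario, rng_seed=seeds[1]
    )
    dates = _event_dates(truth, config.n_events)
    scan_cfg = config.scan_config()
    event_seeds = np.random.SeedSequence(seeds[2]).spawn(len(dates))

    frames = []
    clouds_by_date: dict = {}
    meta = design.to_frame()[["plot_id", "row", "col"]]
    for date, ess in zip(dates, event_seeds):
        s_scan, s_agb, s_ndvi = (
            int(s.generate_state(1)[0] % (2**31)) for s in ess.spawn(3)
        )
        if keep_clouds or any(t in config.traits for t in LIDAR_TRAITS):
            clouds = simulate_scan(design, truth, date, scan_cfg, rng_seed=s_scan)
            if keep_clouds:
                clouds_by_date[date] = clouds
            lidar = extract_traits(clouds, design, config, date)
            frames.append(lidar[lidar["trait"].isin(config.traits)])
        if "agb" in config.traits:
            frames.append(
                simulate_agb(
                    design, truth, date, config.quadrat_area, rng_seed=s_agb
                ).merge(meta, on="plot_id")
            )
        if "ndvi" in config.traits:
            frames.append(
                simulate_ndvi(design, truth, date, rng_seed=s_ndvi).merge(
                    meta, on="plot_id"
                )
            )
    traits = pd.concat(frames, ignore_index=True)
    if keep_clouds:
        return design, truth, dates, traits, clouds_by_date
    return design, truth, dates, traits


def _diagnostics(vc) -> dict:
    res = vc.residuals
    out = {"shapiro_w": None, "variance_ratio": None}
    if res is not None and len(res) >= 4 and np.ptp(res) > 0:
        out["shapiro_w"] = round(float(sps.shapiro(res).statistic), 6)
        order = np.argsort(vc.fitted)
        half = len(res) // 2
        lo = float(np.var(res[order[:half]]))
        hi = float(np.var(res[order[half:]]))
        if min(lo, hi) > 0:
            out["variance_ratio"] = round(max(lo, hi) / min(lo, hi), 6)
    return out


def _fit_event(traits: pd.DataFrame, trait: str, date, config: RunConfig):
    sub = traits[(traits["trait"] == trait) & (traits["date"] == date)]
    return fit_random_effects(
        sub,
        include_trend=config.include_trend,
        nrep_method=config.nrep_method,
    )


def _corr_dict(c) -> dict:
    return {
        "r": None if np.isnan(c.r) else round(c.r, 6),
        "p_value": float(f"{c.p_value:.6g}"),
        "stars": c.stars,
        "n": c.n,
    }


def run_event_analysis(config: RunConfig, out_dir=None, *, _bundle=None) -> dict:
    """Per-event repeatabilities and BLUP correlations for every trait.

    Returns (and optionally writes) a report with, per sampling event, the
    variance components and repeatability of each trait and the Pearson
    correlations of every trait's BLUPs against the AGB BLUPs.
    """
    design, truth, dates, traits = _bundle or _simulate_and_extract(config)
    report: dict = {
        "scenario": config.scenario,
        "seed": config.seed,
        "config_hash": config.config_hash,
        "n_plots": design.n_plots,
        "mean_replication": round(design.mean_replication, 4),
        "events": {},
    }
    blups_by_event: dict = {}
    for date in dates:
        key = date.isoformat()
        entry: dict = {"repeatability": {}, "variance_components": {},
                       "diagnostics": {}, "correlations": {}}
        blups = {}
        for trait in config.traits:
            vc = _fit_event(traits, trait, date, config)
            blups[trait] = vc.blups
            entry["repeatability"][trait] = round(vc.rho, 6)
            entry["variance_components"][trait] = {
                "sigma2_g": float(f"{vc.sigma2_g:.6g}"),
                "sigma2_row": float(f"{vc.sigma2_row:.6g}"),
                "sigma2_col": float(f"{vc.sigma2_col:.6g}"),
                "sigma2_e": float(f"{vc.sigma2_e:.6g}"),
                "nrep": round(vc.nrep, 4),
                "converged": vc.converged,
            }
            diag = _diagnostics(vc)
            entry["diagnostics"][trait] = diag
            log.info(
                "event %s trait %-6s rho=%.3f shapiro_w=%s var_ratio=%s",
                key, trait, vc.rho, diag["shapiro_w"], diag["variance_ratio"],
            )
        if "agb" in blups:
            for trait in config.traits:
                if trait == "agb":
                    continue
                entry["correlations"][f"agb~{trait}"] = _corr_dict(
                    correlate_blups(blups["agb"], blups[trait])
                )
        report["events"][key] = entry
        blups_by_event[key] = blups

    if out_dir is not None:
        _write_outputs(config, design, truth, traits, report, out_dir)
    return report


def run_cgr_analysis(config: RunConfig, out_dir=None, *, _bundle=None) -> dict:
    """Repeatability of crop growth rate per trait, and CGR correlations.

    CGR is computed per plot over each genotype's GS31→GS65 window (values
    interpolated to the phenology dates), then analysed with the same
    random-effects model; AGB-CGR BLUPs are correlated against each LiDAR
    index's CGR BLUPs.
    """
    design, truth, dates, traits = _bundle or _simulate_and_extract(config)
    phen = truth.phenology_frame()
    meta = design.to_frame()[["plot_id", "row", "col"]]
    report: dict = {
        "scenario": config.scenario,
        "seed": config.seed,
        "config_hash": config.config_hash,
        "cgr": {"repeatability": {}, "variance_components": {}, "correlations": {}, "n_plots": {}},
    }
    blups = {}
    cgr_traits = [t for t in config.traits if t != "ndvi"]
    for trait in cgr_traits:
        table = cgr_table(traits, phen, trait).merge(meta, on="plot_id")
        vc = fit_random_effects(
            table, include_trend=config.include_trend, nrep_method=config.nrep_method
        )
        blups[trait] = vc.blups
        report["cgr"]["repeatability"][trait] = round(vc.rho, 6)
        report["cgr"]["n_plots"][trait] = int(len(table))
        report["cgr"]["variance_components"][trait] = {
            "sigma2_g": float(f"{vc.sigma2_g:.6g}"),
            "sigma2_e": float(f"{vc.sigma2_e:.6g}"),
            "nrep": round(vc.nrep, 4),
            "converged": vc.converged,
        }
    if "agb" in blups:
        for trait in cgr_traits:
            if trait == "agb":
                continue
            report["cgr"]["correlations"][f"agb~{trait}"] = _corr_dict(
                correlate_blups(blups["agb"], blups[trait])
            )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _dump_json(report, out / "cgr_report.json")
    return report


def run_all(config: RunConfig, out_dir=None) -> dict:
    """Full pipeline: event analysis plus CGR analysis in one report."""
    bundle = _simulate_and_extract(config)
    report = run_event_analysis(config, _bundle=bundle)
    report["cgr"] = run_cgr_analysis(config, _bundle=bundle)["cgr"]
    if out_dir is not None:
        design, truth, _, traits = bundle
        _write_outputs(config, design, truth, traits, report, out_dir)
    return report


def _dump_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=2, default=str) + "\n")


def _write_csv(df: pd.DataFrame, path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config={config_hash}\n")
        df.to_csv(fh, index=False)


def _write_outputs(config, design, truth, traits, report, out_dir) -> None:
    out = Path(out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    h = config.config_hash
    _dump_json(config.to_dict(), out / "config.json")
    write_design(design, out / "tables" / "design.csv")
    _write_csv(traits, out / "tables" / "traits.csv", h)
    _write_csv(truth.phenology_frame(), out / "tables" / "phenology.csv", h)
    rep_rows = [
        {"date": date, "trait": t, "repeatability": rho}
        for date, entry in report["events"].items()
        for t, rho in entry["repeatability"].items()
    ]
    _write_csv(pd.DataFrame(rep_rows), out / "tables" / "repeatability.csv", h)
    _dump_json(report, out / "report.json")
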