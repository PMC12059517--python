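"""End-to-end pipeline: simulate -> parse -> statistics -> dose -> gamma
-> Lambda/Gamma series -> timing, driven by one validated config file.

Every stage writes its artifacts under the run directory, and a manifest
(config hash, seed, package version) makes any run reproducible.  The
plan report mirrors the clinical summary table: mean/worst spot position
accuracy and reproducibility, mean/min Gamma(1%/1 mm) and Lambda(1 mm),
their Pearson correlation, and delivery-time statistics.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import __version__
from .dose import BeamModel, DoseGrid, build_logfile_plan, reconstruct_dose
from .errors import ConfigError
from .gamma import GammaCriteria
from .logfile_io import (
    events_filename,
    read_fraction,
    record_filename,
    write_fraction_logs,
)
from .machine import ErrorModelConfig, MachineGeometry
from .passrates import PassRateSeries, build_series
from .plans import generate_plan
from .simulate import simulate_course
from .spotstats import aggregate, aggregate_table, compute_spot_statistics
from .timing import decompose_fraction_timing, timing_summary, timing_table


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PlanBlock(_Strict):
    plan_id: str = "synthetic"
    n_fields: int = 2
    gantry_angles: list[float] = [90.0, 270.0]
    layers_per_field: int = 5
    spots_per_layer: int = 80
    target_radius: float = 40.0
    energy_min: float = 85.0
    energy_max: float = 110.0


class GeometryBlock(_Strict):
    sad_x: float = 2300.0
    sad_y: float = 1800.0
    z_ic: float = 450.0
    strip_pitch: float = 2.0
    n_strips: int = 64
    calibration_factor: float = 3.0
    ref_pressure: float = 1013.25
    ref_temperature: float = 293.15

    def build(self) -> MachineGeometry:
        return MachineGeometry(**self.model_dump())


class ErrorBlock(_Strict):
    x_offset_amplitude: float = 0.5
    x_offset_angle_profile: str = "sin"
    y_row_offset: float = 0.3
    layer_tune_shift_sd: float = 0.1
    position_noise_sd: float = 0.15
    edge_highmu_noise_multiplier: float = 2.0
    highmu_threshold: float = 0.1
    mu_noise_sd: float = 0.0005
    mu_bias: float = 0.0001
    drill_time_per_mu: float = 100.0
    spot_switch_time: tuple[float, float] = (2.0, 0.2)
    energy_switch_time: tuple[float, float] = (1.0, 0.2)
    interlock_probability_per_field: float = 0.072
    interlock_duration: tuple[float, float] = (30.0, 10.0)
    pressure_sd: float = 5.0
    temperature_sd: float = 1.0

    def build(self, rng_seed: int) -> ErrorModelConfig:
        return ErrorModelConfig(rng_seed=rng_seed, **self.model_dump())


class DoseBlock(_Strict):
    grid_half_size: float = 60.0
    grid_spacing: float = 3.0
    entry_depth: float = 40.0
    alpha: float = 0.022
    p: float = 1.77
    bragg_width: float = 6.0
    sigma0: float = 4.0
    sigma_growth: float = 0.02

    def build_beam(self) -> BeamModel:
        return BeamModel(alpha=self.alpha, p=self.p,
                         bragg_width=self.bragg_width, sigma0=self.sigma0,
                         sigma_growth=self.sigma_growth)

    def build_grid(self) -> DoseGrid:
        return DoseGrid.empty(self.grid_half_size, self.grid_spacing)


class AnalysisBlock(_Strict):
    tolerance_d: float = 1.0
    gamma_dose_percent: float = 1.0
    gamma_dta: float = 1.0
    gamma_cutoff_fraction: float = 0.10
    gamma_interp_fraction: float = 0.10
    reference_kinds: list[str] = ["original_plan", "first_fraction"]

    def build_criteria(self) -> GammaCriteria:
        return GammaCriteria(
            dose_percent=self.gamma_dose_percent, dta=self.gamma_dta,
            cutoff_fraction=self.gamma_cutoff_fraction,
            interp_fraction=self.gamma_interp_fraction,
        )


class RunBlock(_Strict):
    n_fractions: int = 20
    seed: int = 0


class PipelineConfig(_Strict):
    plan: PlanBlock = PlanBlock()
    geometry: GeometryBlock = GeometryBlock()
    errors: ErrorBlock = ErrorBlock()
    dose: DoseBlock = DoseBlock()
    analysis: AnalysisBlock = AnalysisBlock()
    run: RunBlock = RunBlock()


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML/JSON pipeline config.

    Unknown keys are rejected with the offending field path in the error.
    """
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) or {}
    try:
        return PipelineConfig.model_validate(data)
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(p) for p in e["loc"]) + f": {e['msg']}"
            for e in exc.errors()
        )
        raise ConfigError(f"invalid config {path}: {locs}") from exc


@dataclass
class PlanReport:
    """One summary row per plan (clinical report schema)."""

    plan_id: str
    mean_mu_x: float
    worst_mu_x: float
    mean_mu_y: float
    worst_mu_y: float
    mean_sigma_x: float
    worst_sigma_x: float
    mean_sigma_y: float
    worst_sigma_y: float
    mean_gamma: float
    min_gamma: float
    mean_lambda: float
    min_lambda: float
    pearson_r: float | None
    mean_delivery_time: float
    sd_delivery_time: float


REPORT_COLUMNS = [
    ("plan_id", "{}"),
    ("mean_mu_x", "{:.1f}"), ("worst_mu_x", "{:.1f}"),
    ("mean_mu_y", "{:.1f}"), ("worst_mu_y", "{:.1f}"),
    ("mean_sigma_x", "{:.1f}"), ("worst_sigma_x", "{:.1f}"),
    ("mean_sigma_y", "{:.1f}"), ("worst_sigma_y", "{:.1f}"),
    ("mean_gamma", "{:.1f}"), ("min_gamma", "{:.1f}"),
    ("mean_lambda", "{:.1f}"), ("min_lambda", "{:.1f}"),
    ("pearson_r", "{:.2f}"),
    ("mean_delivery_time", "{:.2f}"), ("sd_delivery_time", "{:.2f}"),
]


def render_report(reports: list[PlanReport], fmt: str = "csv") -> str:
    """Render plan reports as CSV, JSON or aligned text.

    Numeric formatting is fixed (positions 1 decimal mm, rates 1 decimal
    %, times 2 decimals s); an undefined Pearson r renders as ``NA``.
    """
    if not reports:
        raise ConfigError("no reports to render")
    rows = []
    for r in reports:
        row = {}
        for name, f in REPORT_COLUMNS:
            v = getattr(r, name)
            row[name] = "NA" if v is None else f.format(v)
        rows.append(row)
    if fmt == "csv":
        header = ",".join(n for n, _ in REPORT_COLUMNS)
        lines = [header] + [
            ",".join(row[n] for n, _ in REPORT_COLUMNS) for row in rows
        ]
        return "\n".join(lines) + "\n"
    if fmt == "json":
        return json.dumps(rows, indent=1) + "\n"
    if fmt == "text":
        widths = {
            n: max(len(n), *(len(row[n]) for row in rows))
            for n, _ in REPORT_COLUMNS
        }
        lines = ["  ".join(n.ljust(widths[n]) for n, _ in REPORT_COLUMNS)]
        for row in rows:
            lines.append(
                "  ".join(row[n].ljust(widths[n]) for n, _ in REPORT_COLUMNS)
            )
        return "\n".join(lines) + "\n"
    raise ConfigError(f"unknown report format {fmt!r}")


def parse_report_csv(text: str) -> list[PlanReport]:
    """Inverse of :func:`render_report` for the CSV format."""
    lines = [ln for ln in text.strip().splitlines() if ln]
    header = lines[0].split(",")
    reports = []
    for ln in lines[1:]:
        d = dict(zip(header, ln.split(",")))
        kwargs = {}
        for name, _ in REPORT_COLUMNS:
            v = d[name]
            if name == "plan_id":
                kwargs[name] = v
            elif v == "NA":
                kwargs[name] = None
            else:
                kwargs[name] = float(v)
        reports.append(PlanReport(**kwargs))
    return reports


def run_pipeline(
    config_path: str | Path,
    outdir: str | Path,
    seed: int | None = None,
    *,
    quiet: bool = False,
) -> PlanReport:
    """Run the full LFQA pipeline from one config file.

    Writes plan files, per-fraction logs, per-spot statistics, dose grids,
    pass-rate series, timing tables, the plan report and a run manifest
    under ``outdir``.  ``seed`` overrides the config's run seed.
    """
    cfg = load_config(config_path)
    seed = cfg.run.seed if seed is None else seed
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    def log(msg: str) -> None:
        if not quiet:
            print(f"[pbs-lfqa] {msg}")

    geometry = cfg.geometry.build()
    errors = cfg.errors.build(rng_seed=seed)
    beam = cfg.dose.build_beam()
    criteria = cfg.analysis.build_criteria()

    # 1. plan
    log("generating plan")
    plan = generate_plan(
        cfg.plan.n_fields, cfg.plan.gantry_angles, cfg.plan.layers_per_field,
        cfg.plan.spots_per_layer, cfg.plan.target_radius, rng_seed=seed,
        energy_range=(cfg.plan.energy_min, cfg.plan.energy_max),
        plan_id=cfg.plan.plan_id,
    )
    plan.save_json(out / "plan.json")
    plan.save_csv(out / "plan.csv")

    # 2. simulate + write logs
    log(f"simulating {cfg.run.n_fractions} fractions")
    simulated = simulate_course(plan, geometry, errors, cfg.run.n_fractions)
    logdir = out / "logs"
    for fx in simulated:
        write_fraction_logs(fx, plan, geometry, logdir)

    # 3. read back through the parser (the analysis sees only files)
    fractions = []
    for fx in simulated:
        recs = [logdir / record_filename(fx.fraction_index, fid)
                for fid in fx.field_ids]
        evs = [logdir / events_filename(fx.fraction_index, fid)
               for fid in fx.field_ids]
        fractions.append(
            read_fraction(recs, evs, plan, geometry,
                          fraction_index=fx.fraction_index)
        )

    # 4. spot statistics
    log("computing spot statistics")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stats = compute_spot_statistics(plan, fractions)
    stats.to_csv(out / "spot_statistics.csv", index=False)
    aggregate_table(stats, "plan").to_csv(out / "summary_plan.csv", index=False)
    aggregate_table(stats, "gantry_angle").to_csv(
        out / "summary_gantry.csv", index=False
    )
    agg = aggregate(stats, "plan")["plan"]

    # 5. dose reconstruction (reference + per fraction)
    log("reconstructing doses")
    grid = cfg.dose.build_grid()
    ref_dose = reconstruct_dose(plan, grid, beam, cfg.dose.entry_depth)
    dosedir = out / "dose"
    dosedir.mkdir(exist_ok=True)
    ref_dose.save(dosedir / "reference")
    usable = [f for f in fractions if not f.aborted]
    fraction_doses = []
    for f in usable:
        d = reconstruct_dose(build_logfile_plan(plan, f), grid, beam,
                             cfg.dose.entry_depth)
        d.save(dosedir / f"fraction{f.fraction_index:03d}")
        fraction_doses.append(d)

    # 6. pass-rate series per reference kind
    series: dict[str, PassRateSeries] = {}
    for kind in cfg.analysis.reference_kinds:
        log(f"pass rates vs {kind}")
        series[kind] = build_series(
            plan, fractions, reference_kind=kind,
            tolerance_d=cfg.analysis.tolerance_d, criteria=criteria,
            grid=grid, beam=beam, entry_depth=cfg.dose.entry_depth,
            fraction_doses=fraction_doses,
            reference_dose=ref_dose if kind == "original_plan" else None,
        )
        pd.DataFrame({
            "fraction_index": series[kind].fraction_indices,
            "lambda_percent": series[kind].lambda_percent,
            "gamma_percent": series[kind].gamma_percent,
        }).to_csv(out / f"passrates_{kind}.csv", index=False)
    (out / "passrates_summary.json").write_text(
        json.dumps({k: s.summary() for k, s in series.items()}, indent=1)
    )

    # 7. timing
    log("timing analysis")
    breakdowns = [bd for f in usable for bd in decompose_fraction_timing(f)]
    timing_table(breakdowns).to_csv(out / "timing.csv", index=False)
    tsum = timing_summary(breakdowns)

    # 8. report + manifest
    main = series.get("original_plan") or next(iter(series.values()))
    report = PlanReport(
        plan_id=plan.plan_id,
        mean_mu_x=agg["mu_x"]["mean"], worst_mu_x=agg["mu_x"]["worst"],
        mean_mu_y=agg["mu_y"]["mean"], worst_mu_y=agg["mu_y"]["worst"],
        mean_sigma_x=agg["sigma_x"]["mean"], worst_sigma_x=agg["sigma_x"]["worst"],
        mean_sigma_y=agg["sigma_y"]["mean"], worst_sigma_y=agg["sigma_y"]["worst"],
        mean_gamma=float(np.mean(main.gamma_percent)),
        min_gamma=float(np.min(main.gamma_percent)),
        mean_lambda=float(np.mean(main.lambda_percent)),
        min_lambda=float(np.min(main.lambda_percent)),
        pearson_r=main.pearson_r,
        mean_delivery_time=tsum.plan_mean,
        sd_delivery_time=tsum.plan_two_sigma / 2.0
        if np.isfinite(tsum.plan_two_sigma) else float("nan"),
    )
    (out / "report.csv").write_text(render_report([report], "csv"))
    (out / "report.json").write_text(render_report([report], "json"))

    manifest = {
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.model_dump(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": seed,
        "package_version": __version__,
        "n_fractions": cfg.run.n_fractions,
        "n_spots": plan.n_spots,
        "interlock_free_percent": tsum.interlock_free_percent,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log("done")
    return report
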