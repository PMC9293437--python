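"""End-to-end orchestration: simulate → process → status → fit → partition.

Each stage reads and writes plain CSV files inside a run directory, so a
run is auditable and any stage can be re-executed in isolation.  A JSON
manifest records the configuration hash, the seeds, per-file checksums
and the convergence summary; two runs from the same configuration yield
identical manifests.

Every constant of the measurement protocol (standard knowns −4.4/−19.5‰,
reference water −8.2‰, the 6000-ppm floor, the 100-µm TWD and 0.12 VWC
drought thresholds, the MCMC settings) surfaces here as a configurable
default rather than a buried literal.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import isotope_processing as iso
from . import mixing_model as mm
from . import synthetic_data as synth
from . import tree_water_status as tws
from . import uptake_partitioning as up

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "process_stage", "status_stage", "fit_stage", "partition_stage"]

log = logging.getLogger("isoroot")


@dataclass(frozen=True)
class RunConfig:
    """Structured configuration for a full pipeline run."""

    sim: synth.SimConfig = field(default_factory=synth.SimConfig)
    mcmc: mm.MCMCSettings = field(default_factory=mm.MCMCSettings)
    standard_knowns: tuple[float, float] = iso.DEFAULT_STANDARD_KNOWNS
    reference_delta: float = iso.DEFAULT_REFERENCE_DELTA
    ppm_floor: float = iso.DEFAULT_PPM_FLOOR
    twd_threshold_um: float = 100.0
    vwc_threshold: float = 0.12
    rain_threshold_mm: float = 20.0
    min_sigma: float = 0.1  # ‰ floor on daily source SDs
    report_adjusted: bool = False  # report p′ instead of p
    seed: int = 0

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                obj = dataclasses.asdict(obj)
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            if isinstance(obj, (tuple, list)):
                return [convert(v) for v in obj]
            if isinstance(obj, date):
                return obj.isoformat()
            return obj

        return convert(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "sim" in data:
            sim = dict(data["sim"])
            for key in ("season_start", "season_end"):
                if isinstance(sim.get(key), str):
                    sim[key] = date.fromisoformat(sim[key])
            if isinstance(sim.get("drought_window"), (list, tuple)):
                sim["drought_window"] = tuple(
                    date.fromisoformat(d) if isinstance(d, str) else d for d in sim["drought_window"]
                )
            for key in (
                "depths_cm",
                "layer_boundaries_cm",
                "root_profile",
                "initial_vwc",
                "initial_delta",
                "sapwood_areas_cm2",
                "crown_areas_m2",
                "dbh_cm",
                "precip_delta_range",
            ):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if isinstance(sim.get("instrument_bias"), dict):
                sim["instrument_bias"] = synth.InstrumentBias(**sim["instrument_bias"])
            if isinstance(sim.get("proportion_nodes"), list):
                sim["proportion_nodes"] = tuple(
                    (date.fromisoformat(d) if isinstance(d, str) else d, tuple(p))
                    for d, p in sim["proportion_nodes"]
                )
            data["sim"] = synth.SimConfig(**sim)
        if "mcmc" in data:
            data["mcmc"] = mm.MCMCSettings(**data["mcmc"])
        if "standard_knowns" in data:
            data["standard_knowns"] = tuple(data["standard_knowns"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index_label is not None, index_label=index_label, float_format="%.8g")


# ---------------------------------------------------------------------------
# stages


def simulate_stage(config: RunConfig, outdir: Path) -> synth.SimTruth:
    truth = synth.generate_season(config.sim)
    obs = synth.emit_observations(truth)
    _write_csv(obs["probe_readings"], outdir / "probe_readings.csv")
    _write_csv(obs["stem_radius"], outdir / "stem_radius.csv", index_label="timestamp")
    _write_csv(obs["sap_flux"], outdir / "sap_flux.csv", index_label="timestamp")
    _write_csv(obs["soil_moisture"], outdir / "soil_moisture.csv", index_label="timestamp")
    _write_csv(obs["lab_calibration"], outdir / "lab_calibration.csv")
    _write_csv(truth.forcing, outdir / "forcing.csv", index_label="timestamp")
    # ground truth for validation
    k = truth.config.n_layers
    truth_df = pd.DataFrame(
        {
            **{f"p_true_{j}": truth.p_true[:, j] for j in range(k)},
            **{f"vwc_{j}": truth.vwc_daily[:, j] for j in range(k)},
            **{f"delta_{j}": truth.delta_daily[:, j] for j in range(k)},
            **{f"e_tree_{t}": truth.transpiration[:, t] for t in range(truth.config.n_trees)},
            **{f"twd_tree_{t}": truth.twd[:, t] for t in range(truth.config.n_trees)},
        },
        index=truth.dates,
    )
    _write_csv(truth_df, outdir / "truth_daily.csv", index_label="date")
    meta = {"seed": truth.seed, "config": config.to_dict()}
    (outdir / "truth_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    log.info("simulate: %d probe readings, %d days", len(obs["probe_readings"]), truth.config.n_days)
    return truth


def process_stage(config: RunConfig, outdir: Path) -> dict[str, pd.DataFrame]:
    """Raw vapour readings → calibrated liquid δ18O daily summaries."""
    readings = pd.read_csv(outdir / "probe_readings.csv", parse_dates=["timestamp"])
    lab = pd.read_csv(outdir / "lab_calibration.csv")

    curve = iso.fit_concentration_correction(
        list(zip(lab["ppm"], lab["measured"])), known_delta=config.reference_delta
    )
    readings["delta_corr"] = curve.apply(readings["delta_vapour"].to_numpy(), readings["h2o_ppm"].to_numpy())

    standards = readings[readings["kind"] == "standard"].copy()
    if standards.empty:
        raise ValueError("no standard readings found; cannot calibrate cycles")
    # knowns are liquid; compare in vapour space at the container temperature
    standards["known"] = iso.liquid_to_vapour(
        standards["known"].to_numpy(), standards["temperature"].to_numpy()
    )
    samples = readings[readings["kind"] != "standard"].copy()
    calibrated = iso.calibrate_series(samples, standards, delta_col="delta_corr")
    calibrated["delta_liquid"] = iso.vapour_to_liquid(
        calibrated["delta_calibrated"].to_numpy(), calibrated["temperature"].to_numpy()
    )

    rs_mean = float(standards["r_s"].mean())
    rs_sd = float(standards["r_s"].std(ddof=1))
    calibrated["low_ppm"] = calibrated["h2o_ppm"] < config.ppm_floor
    calibrated["contaminated"] = calibrated["r_s"] > rs_mean + rs_sd

    # pool the two soil profiles per depth before daily aggregation
    calibrated["series_id"] = np.where(
        calibrated["kind"] == "soil",
        "soil_" + calibrated["probe_id"].str.rsplit("_", n=1).str[1],
        calibrated["probe_id"],
    )
    daily = iso.daily_summaries(
        calibrated.rename(columns={"probe_id": "raw_probe_id", "series_id": "probe_id"})
    )
    qc = daily.rename(columns={"probe_id": "series_id"})
    _write_csv(calibrated.drop(columns=["series_id"]), outdir / "calibrated_readings.csv")
    _write_csv(qc, outdir / "daily_isotopes.csv")
    log.info(
        "process: %d readings calibrated, correction fit R²=%.4f, %d flagged low-ppm, %d contaminated",
        len(calibrated),
        curve.r_squared,
        int(calibrated["low_ppm"].sum()),
        int(calibrated["contaminated"].sum()),
    )
    return {"calibrated": calibrated, "daily": qc}


def status_stage(config: RunConfig, outdir: Path) -> dict:
    """Dendrometer and sap-flux streams → TWD, transpiration, drought window."""
    sr = pd.read_csv(outdir / "stem_radius.csv", parse_dates=["timestamp"], index_col="timestamp")
    fd = pd.read_csv(outdir / "sap_flux.csv", parse_dates=["timestamp"], index_col="timestamp")
    vwc = pd.read_csv(outdir / "soil_moisture.csv", parse_dates=["timestamp"], index_col="timestamp")
    forcing = pd.read_csv(outdir / "forcing.csv", parse_dates=["timestamp"], index_col="timestamp")
    sim = config.sim

    twd_daily = pd.DataFrame({c: tws.daily_mean_twd(sr[c]) for c in sr.columns})
    e_daily = pd.DataFrame(
        {
            c: tws.daily_transpiration(
                fd[c],
                sim.sapwood_areas_cm2[i % len(sim.sapwood_areas_cm2)],
                sim.crown_areas_m2[i % len(sim.crown_areas_m2)],
            )["e_mm"]
            for i, c in enumerate(fd.columns)
        }
    )
    topsoil_col = f"vwc_{sim.depths_cm[0]:g}cm"
    vwc_daily = vwc.groupby(vwc.index.normalize()).mean()
    precip_daily = forcing["precip_mm"].groupby(forcing.index.normalize()).sum()
    seg = tws.classify_drought_period(
        twd_daily,
        vwc_daily[topsoil_col],
        precip_daily,
        twd_threshold=config.twd_threshold_um,
        vwc_threshold=config.vwc_threshold,
        rain_threshold=config.rain_threshold_mm,
    )
    _write_csv(twd_daily, outdir / "twd_daily.csv", index_label="date")
    _write_csv(e_daily, outdir / "transpiration_daily.csv", index_label="date")
    _write_csv(vwc_daily, outdir / "vwc_daily.csv", index_label="date")
    seg_out = {
        "start": str(seg.start.date()) if seg.start is not None else None,
        "end": str(seg.end.date()) if seg.end is not None else None,
        "twd_threshold_um": seg.twd_threshold,
        "vwc_threshold": seg.vwc_threshold,
        "rain_threshold_mm": seg.rain_threshold,
        "end_is_season_end": seg.end_is_season_end,
    }
    (outdir / "drought_segmentation.json").write_text(json.dumps(seg_out, indent=2))
    log.info("status: drought window %s → %s", seg_out["start"], seg_out["end"])
    return {"twd": twd_daily, "e": e_daily, "vwc": vwc_daily, "precip": precip_daily, "segmentation": seg}


def fit_stage(config: RunConfig, outdir: Path) -> dict:
    """Daily Bayesian mixing-model fits across the season."""
    daily = pd.read_csv(outdir / "daily_isotopes.csv", parse_dates=["day"])
    vwc_daily = pd.read_csv(outdir / "vwc_daily.csv", parse_dates=["date"], index_col="date")
    sim = config.sim
    prior = mm.build_prior(sim.root_profile, sim.layer_boundaries_cm)

    depth_labels = [f"soil_{d:g}cm" for d in sim.depths_cm]
    vwc_cols = [f"vwc_{d:g}cm" for d in sim.depths_cm]
    soil = daily[daily["series_id"].isin(depth_labels)]
    xylem = daily[daily["series_id"].str.startswith("tree_")]

    sources_by_day: dict[pd.Timestamp, mm.SourceDay] = {}
    for day, grp in soil.groupby("day"):
        grp = grp.set_index("series_id").reindex(depth_labels)
        if grp["mean"].isna().any() or day not in vwc_daily.index:
            continue
        if (grp["n"] == 0).any():
            continue
        sources_by_day[day] = mm.SourceDay(
            date=day,
            mu=grp["mean"].to_numpy(),
            sigma=np.maximum(grp["sd"].to_numpy(), config.min_sigma),
            concentration=vwc_daily.loc[day, vwc_cols].to_numpy(),
            n=grp["n"].to_numpy(),
        )
    xylem_by_day = {
        day: grp.loc[grp["n"] > 0, "mean"].dropna().tolist() for day, grp in xylem.groupby("day")
    }

    posteriors, skipped = mm.fit_season(xylem_by_day, sources_by_day, prior, config.mcmc)
    table = mm.posterior_table(posteriors)
    _write_csv(table, outdir / "posterior_daily.csv")
    (outdir / "fit_report.json").write_text(
        json.dumps(
            {
                "n_days_fit": len(posteriors),
                "skipped_days": [str(pd.Timestamp(d).date()) for d in skipped],
                "n_converged": int(sum(p.converged for p in posteriors.values())),
                "prior_alpha": prior.alpha.tolist(),
            },
            indent=2,
        )
    )
    log.info("fit: %d days, %d converged, %d skipped", len(posteriors), sum(p.converged for p in posteriors.values()), len(skipped))
    return {"posteriors": posteriors, "skipped": skipped, "prior": prior}


def partition_stage(config: RunConfig, outdir: Path) -> dict:
    """Posterior proportions × transpiration → absolute uptake + analyses."""
    table = pd.read_csv(outdir / "posterior_daily.csv", parse_dates=["date"])
    e_daily = pd.read_csv(outdir / "transpiration_daily.csv", parse_dates=["date"], index_col="date")
    seg = json.loads((outdir / "drought_segmentation.json").read_text())

    value_col = "adjusted_mean" if config.report_adjusted else "mean"
    props = table.pivot(index="date", columns="layer", values=value_col)
    props = props.div(props.sum(axis=1), axis=0)
    sds = table.pivot(index="date", columns="layer", values="sd")
    e_mean = e_daily.mean(axis=1)

    uptake = up.absolute_uptake(props, e_mean, proportion_sd=sds)

    result: dict = {"uptake": uptake}
    periods = None
    if seg["start"] is not None:
        try:
            periods = up.PeriodDefinition.from_drought(
                pd.Timestamp(seg["start"]), pd.Timestamp(seg["end"]), props.index.max()
            )
        except ValueError as exc:
            log.warning("weekly periods undefined for this season: %s", exc)
    if periods is not None:
        labels = periods.label(props.index)
        uptake["period"] = labels.reindex(uptake["date"]).to_numpy()
        result["periods"] = periods
        result["period_labels"] = labels
    if seg["start"] is not None:
        drought_mask = (props.index >= pd.Timestamp(seg["start"])) & (
            props.index <= pd.Timestamp(seg["end"])
        )
        after_mask = props.index > pd.Timestamp(seg["end"])
        layer_names = {c: f"{config.sim.depths_cm[int(c)]:g}cm" for c in props.columns}
        rel = props.rename(columns=layer_names)
        absu = uptake.pivot(index="date", columns="layer", values="uptake_mm").rename(columns=layer_names)
        tables = []
        for name, frame in (("relative", rel), ("absolute", absu)):
            for period, mask in (("during_drought", drought_mask), ("after_drought", after_mask)):
                if int(mask.sum()) >= 3:
                    tab = up.correlation_table(frame, e_mean, pd.Series(mask, index=props.index))
                    tab.insert(0, "series", name)
                    tab.insert(1, "period", period)
                    tables.append(tab)
        if tables:
            corr = pd.concat(tables, ignore_index=True)
            _write_csv(corr, outdir / "correlation_tables.csv")
            result["correlations"] = corr
    _write_csv(uptake, outdir / "uptake_daily.csv")
    log.info("partition: %d uptake rows", len(uptake))
    return result


def report_stage(config: RunConfig, outdir: Path) -> str:
    """Plain-text run summary."""
    lines = ["isoroot run summary", "===================", ""]
    seg_path = outdir / "drought_segmentation.json"
    if seg_path.exists():
        seg = json.loads(seg_path.read_text())
        lines.append(f"drought window: {seg['start']} → {seg['end']}")
    fit_path = outdir / "fit_report.json"
    if fit_path.exists():
        fit = json.loads(fit_path.read_text())
        lines.append(f"mixing-model days fit: {fit['n_days_fit']} (converged {fit['n_converged']})")
    upt_path = outdir / "uptake_daily.csv"
    if upt_path.exists():
        uptake = pd.read_csv(upt_path)
        top = uptake[uptake["layer"] == uptake["layer"].min()]
        lines.append(f"topsoil uptake (mm/d): mean {top['uptake_mm'].mean():.2f}, range "
                     f"[{top['uptake_mm'].min():.2f}, {top['uptake_mm'].max():.2f}]")
    text = "\n".join(lines) + "\n"
    (outdir / "report.txt").write_text(text)
    return text


STAGE_FILES = [
    "probe_readings.csv",
    "stem_radius.csv",
    "sap_flux.csv",
    "soil_moisture.csv",
    "lab_calibration.csv",
    "forcing.csv",
    "truth_daily.csv",
    "calibrated_readings.csv",
    "daily_isotopes.csv",
    "twd_daily.csv",
    "transpiration_daily.csv",
    "vwc_daily.csv",
    "posterior_daily.csv",
    "uptake_daily.csv",
    "correlation_tables.csv",
]


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages in order; returns the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    simulate_stage(config, outdir)
    process_stage(config, outdir)
    status_stage(config, outdir)
    fit = fit_stage(config, outdir)
    partition_stage(config, outdir)
    report_stage(config, outdir)

    checksums = {name: _sha256(outdir / name) for name in STAGE_FILES if (outdir / name).exists()}
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "sim_seed": config.sim.seed,
        "mcmc_seed": config.mcmc.seed,
        "checksums": checksums,
        "n_days_fit": len(fit["posteriors"]),
        "n_converged": int(sum(p.converged for p in fit["posteriors"].values())),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def validate_inputs(paths: dict[str, Path], schemas: dict[str, list[str]] | None = None) -> dict:
    """Schema and sanity checks on input CSVs.

    ``schemas`` maps a logical name to required columns.  Errors:
    unreadable file, missing column, non-monotone timestamps.  Warnings:
    duplicated (probe, timestamp) keys with the offending line numbers.
    """
    default_schema = {
        "probe_readings": ["probe_id", "timestamp", "delta_vapour", "h2o_ppm", "r_s", "temperature"],
        "stem_radius": ["timestamp"],
        "sap_flux": ["timestamp"],
        "soil_moisture": ["timestamp"],
        "forcing": ["timestamp", "t_air", "rh", "precip_mm"],
        "lab_calibration": ["ppm", "measured"],
    }
    schemas = schemas or default_schema
    errors: list[str] = []
    warnings_: list[str] = []
    for name, path in paths.items():
        path = Path(path)
        if not path.exists():
            errors.append(f"{name}: file not found: {path}")
            continue
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            errors.append(f"{name}: unreadable ({exc})")
            continue
        required = schemas.get(name, [])
        missing = [c for c in required if c not in df.columns]
        if missing:
            errors.append(f"{name}: missing columns {missing}")
            continue
        if "timestamp" in df.columns:
            ts = pd.to_datetime(df["timestamp"], errors="coerce")
            bad = df.index[ts.isna()]
            if len(bad):
                errors.append(f"{name}: unparseable timestamp at line {bad[0] + 2}")
                continue
            if "probe_id" in df.columns:
                dup = df.duplicated(subset=["probe_id", "timestamp"], keep=False)
                if dup.any():
                    lines = (df.index[dup] + 2).tolist()[:10]
                    warnings_.append(f"{name}: duplicated (probe_id, timestamp) rows at lines {lines}")
                per_probe_sorted = df.groupby("probe_id")["timestamp"].apply(
                    lambda s: pd.to_datetime(s).is_monotonic_increasing
                )
                if not per_probe_sorted.all():
                    errors.append(f"{name}: non-monotone timestamps within a probe series")
            elif not ts.is_monotonic_increasing:
                errors.append(f"{name}: non-monotone timestamps")
    return {"errors": errors, "warnings": warnings_, "ok": not errors}
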