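"""Readers, writers, session manifests and the pipeline orchestrator.

All CSVs use one dialect: comma separators, '.' decimal, UTF-8, LF line
endings, header required. Readers validate aggressively and name the
offending row — the analysis filters are where silent bugs live, so
malformed input is a typed error, never a silent fix. Every results
directory carries a provenance record (config, config hash, seeds), and
reruns with the same config and seed are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import GeometryError, PositionSeries, SectorSpec
from .units import SpikeTrain

log = logging.getLogger("placeframes")

FLOAT_FMT = "%.10g"

POSITIONS_COLS = ["t_s", "x_room_cm", "y_room_cm", "theta_deg"]
SPIKES_COLS = ["unit_id", "t_s"]
UNITS_COLS = ["unit_id", "waveform_us", "region_tag"]
CO_COLS = ["subject", "group", "region", "od"]


class ValidationError(ValueError):
    """Malformed input file (schema, ordering or range violation)."""


#: Defaults for every tunable named across the analysis modules; a run
#: config overrides these and its hash stamps every output.
DEFAULT_CONFIG: dict = {
    "dt_s": 0.133,
    "episode_len_s": 5.0,
    "zone_width_deg": 60.0,
    "seed_sector_deg": 20.0,
    "near_coverage": 0.5,
    "fdr_q": 0.01,
    "refractory_s": 1.5,
    "min_step_cm": 0.32,
    "bin_cm": 2.5,
    "smoothing_sigma_bins": 1.0,
    "min_occupancy_s": 0.5,
    "sfep_grid": 16,
    "sfep_min_bin_samples": 10,
    "min_spikes": 50,
    "overdispersion_frame": "auto",
}


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path | None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg) - {"zone", "seed", "duration_s", "cells"}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg


def parse_zone(spec: str | None) -> SectorSpec | None:
    """Parse 'frame:center:width' (e.g. 'room:0:60') into a SectorSpec."""
    if spec in (None, "", "none"):
        return None
    parts = spec.split(":")
    if len(parts) != 3:
        raise ValidationError(f"zone spec must be frame:center:width, got {spec!r}")
    frame, center, width = parts
    try:
        return SectorSpec(float(center), float(width), frame)
    except (ValueError, GeometryError) as e:
        raise ValidationError(f"bad zone spec {spec!r}: {e}") from e


def _read_csv(path: str | Path, cols: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df


def read_positions(path: str | Path, arena_radius: float | None = None) -> PositionSeries:
    df = _read_csv(path, POSITIONS_COLS)
    for col in POSITIONS_COLS:
        bad = df.index[~np.isfinite(df[col].to_numpy(dtype=float))]
        if len(bad):
            raise ValidationError(f"{path}: non-finite {col} at row {bad[0] + 2}")
    kwargs = {} if arena_radius is None else {"arena_radius": arena_radius}
    try:
        return PositionSeries(df["t_s"].to_numpy(), df["x_room_cm"].to_numpy(),
                              df["y_room_cm"].to_numpy(), df["theta_deg"].to_numpy(),
                              **kwargs)
    except GeometryError as e:
        raise ValidationError(f"{path}: {e}") from e


def write_positions(series: PositionSeries, path: str | Path) -> None:
    df = pd.DataFrame({"t_s": series.t, "x_room_cm": series.x,
                       "y_room_cm": series.y, "theta_deg": series.theta})
    df.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")


def read_spikes(path: str | Path, units: pd.DataFrame | None = None
                ) -> list[SpikeTrain]:
    """Spike table (`unit_id,t_s`) into per-unit trains.

    Duplicate (unit, t) rows are deduplicated with a logged count; a
    unit present in spikes but absent from the units table is an error.
    """
    df = _read_csv(path, SPIKES_COLS)
    if df.empty:
        log.warning("%s: empty spike file", path)
    n0 = len(df)
    df = df.drop_duplicates()
    if len(df) < n0:
        log.info("%s: dropped %d duplicate spike rows", path, n0 - len(df))
    meta: dict[str, tuple[float | None, str]] = {}
    if units is not None:
        unknown = set(df["unit_id"].astype(str)) - set(units["unit_id"].astype(str))
        if unknown:
            raise ValidationError(f"{path}: spike unit_ids absent from units table: "
                                  f"{sorted(unknown)[:5]}")
        for _, row in units.iterrows():
            wf = row["waveform_us"]
            meta[str(row["unit_id"])] = (
                None if pd.isna(wf) else float(wf),
                str(row.get("region_tag", "unknown")),
            )
    trains = []
    for uid, grp in df.groupby("unit_id", sort=True):
        times = np.sort(grp["t_s"].to_numpy(dtype=float))
        wf, region = meta.get(str(uid), (None, "unknown"))
        trains.append(SpikeTrain(str(uid), times, waveform_us=wf, region=region))
    return trains


def write_spikes(trains: list[SpikeTrain], path: str | Path) -> None:
    rows = [(tr.unit_id, t) for tr in trains for t in tr.spike_times]
    pd.DataFrame(rows, columns=SPIKES_COLS).to_csv(
        path, index=False, float_format=FLOAT_FMT, lineterminator="\n")


def read_units(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, ["unit_id", "waveform_us"])
    if "region_tag" not in df.columns:
        df["region_tag"] = "unknown"
    if df["unit_id"].duplicated().any():
        dup = df.loc[df["unit_id"].duplicated(), "unit_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate unit_id {dup!r}")
    return df


def write_units(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")


def read_co(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, CO_COLS)
    bad = df.index[~np.isfinite(df["od"].to_numpy(dtype=float))]
    if len(bad):
        raise ValidationError(f"{path}: non-finite od at row {bad[0] + 2}")
    return df


PHASES = ("pretraining", "training", "retention", "conflict")


@dataclass
class SessionManifest:
    """One session of the workflow (pretraining/training/retention/conflict).

    Pretraining has no shock zone; conflict sessions derive their zone by
    rotating the initial training zone 180 degrees.
    """

    session_id: str
    phase: str
    positions: str
    spikes: str | None = None
    units: str | None = None
    zone: SectorSpec | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}")
        if self.phase == "pretraining" and self.zone is not None:
            raise ValidationError("pretraining sessions have no shock zone")
        if self.phase in ("training", "retention") and self.zone is None:
            raise ValidationError(f"{self.phase} session requires a zone")

    @classmethod
    def from_dict(cls, d: dict, initial_zone: SectorSpec | None = None
                  ) -> "SessionManifest":
        zone = parse_zone(d.get("zone"))
        if zone is None and d.get("phase") == "conflict":
            if initial_zone is None:
                raise ValidationError(
                    "conflict session without explicit zone needs the initial zone")
            zone = initial_zone.shifted(180.0)
        return cls(session_id=str(d["session_id"]), phase=d["phase"],
                   positions=d["positions"], spikes=d.get("spikes"),
                   units=d.get("units"), zone=zone, seed=d.get("seed"))


@dataclass
class PipelineResult:
    out_dir: Path
    behavior: pd.DataFrame
    unit_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summaries: dict[str, dict] = field(default_factory=dict)


def run_pipeline(manifests: list[SessionManifest], config: dict,
                 out_dir: str | Path) -> PipelineResult:
    """Run behavior for every session and the spike analyses where spikes
    exist; write one results directory with provenance."""
    from . import behavior as bh
    from . import overdispersion as od
    from . import sfep as sf
    from .units import select_pyramidal, unit_metrics_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)

    beh_rows = []
    unit_tables: dict[str, pd.DataFrame] = {}
    summaries: dict[str, dict] = {}
    for m in manifests:
        series = read_positions(m.positions)
        res = bh.behavior_endpoints(series, m.zone,
                                    min_step=config["min_step_cm"],
                                    refractory=config["refractory_s"])
        beh_rows.append({"session_id": m.session_id, "phase": m.phase,
                         "distance_m": res.distance_m,
                         "time_to_first_entry_s": res.time_to_first_entry_s,
                         "first_entry_censored": res.first_entry_censored,
                         "n_entrances": res.n_entrances,
                         "session_length_s": res.session_length_s,
                         "config_hash": chash})
        if m.spikes is None:
            continue
        units_df = read_units(m.units) if m.units else None
        trains = read_spikes(m.spikes, units_df)
        metrics = unit_metrics_table(trains, series.duration)
        metrics["config_hash"] = chash
        unit_tables[m.session_id] = metrics
        write_units(metrics, out / f"{m.session_id}_unit_metrics.csv")

        pyr = select_pyramidal(trains, series.duration,
                               min_spikes=config["min_spikes"])
        log.info("session %s: %d/%d units enter place analyses",
                 m.session_id, len(pyr), len(trains))
        if not pyr:
            continue

        od_rows = []
        for tr in pyr:
            r = od.cell_overdispersion(
                tr, series, frame=config["overdispersion_frame"],
                episode_len=config["episode_len_s"], bin_cm=config["bin_cm"],
                smoothing_sigma=config["smoothing_sigma_bins"],
                min_occupancy=config["min_occupancy_s"])
            od_rows.append({"unit_id": tr.unit_id, "frame": r["frame"],
                            "var_z": r["var_z"], "n_retained": r["n_retained"],
                            "retention_fraction": r["retention_fraction"]})
        od_df = pd.DataFrame(od_rows)
        od_df["config_hash"] = chash
        od_df.to_csv(out / f"{m.session_id}_overdispersion.csv", index=False,
                     float_format=FLOAT_FMT, lineterminator="\n")

        pref, windows = sf.ensemble_preference(
            pyr, series, dt=config["dt_s"], n_grid=config["sfep_grid"],
            min_samples=config["sfep_min_bin_samples"])
        summary = {"sfep_room": pref.sfep_room, "runs_z": pref.runs_z,
                   "n_cells": pref.n_cells, "n_windows": pref.n_windows_used}
        pd.DataFrame({"t_center_s": windows.t_center,
                      "ensemble_delta_i": pref.delta_i}).to_csv(
            out / f"{m.session_id}_sfep_series.csv", index=False,
            float_format=FLOAT_FMT, lineterminator="\n")
        pmap = sf.preference_map(pref, windows,
                                 min_samples=config["sfep_min_bin_samples"])
        pd.DataFrame(pmap.grid()).to_csv(
            out / f"{m.session_id}_preference_map.csv", index=False,
            float_format=FLOAT_FMT, lineterminator="\n")
        if m.zone is not None:
            from .geometry import near_far_partition
            near, far = near_far_partition(series,
                                           seed_width=config["seed_sector_deg"],
                                           coverage=config["near_coverage"])
            try:
                p_near, p_far = sf.near_far_summary(pmap, windows, near, far)
                summary.update({"p_room_near": p_near, "p_room_far": p_far,
                                "near_center_deg": near.center_deg,
                                "near_width_deg": near.width_deg})
            except sf.SfepError as e:
                log.warning("session %s: near/far summary unavailable (%s)",
                            m.session_id, e)
        summaries[m.session_id] = summary

    behavior_df = pd.DataFrame(beh_rows)
    behavior_df.to_csv(out / "behavior_endpoints.csv", index=False,
                       float_format=FLOAT_FMT, lineterminator="\n")
    provenance = {"config": config, "config_hash": chash,
                  "sessions": [{"session_id": m.session_id, "phase": m.phase,
                                "seed": m.seed} for m in manifests],
                  "summaries": summaries}
    with open(out / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True, default=str)
    return PipelineResult(out, behavior_df, unit_tables, summaries)
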