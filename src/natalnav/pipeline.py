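"""End-to-end orchestration: config, stages, and table artifacts.

A run is a validated :class:`RunConfig` plus an ordered list of stages:

``simulate``      generate a synthetic world and track (seeded),
``segment``       split the track into constant-course segments,
``winddrift``     decompose hourly steps against the wind field and fit
                  the drift regressions,
``magtransform``  evaluate the magnetic field along the track and emit
                  nest-origin coordinates,
``compare``       pairwise coefficient tests across coordinate spaces,
``report``        summary statistics over the packaged reference tables
                  and over anything computed upstream.

Every CSV artifact is written with a provenance header (config hash,
package version), and identical configs byte-reproduce all outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__, fixtures
from .geodesy import EARTH_RADIUS_KM, GeoPoint
from .magframe import DipoleModel, ElementGrid, NatalFrame, natal_transform
from .spacecompare import (
    natal_straightness_table,
    pairwise_coefficient_tests,
    trace_tracks,
)
from .synthdata import SyntheticWorld, TruthManifest, WindFieldParams, make_track, make_world
from .trackseg import GeoFix, read_track_csv, segment_track, write_summary_table
from .winddrift import WindField, decompose_segment, drift_regressions, overcompensation_fraction

__all__ = ["RunConfig", "SimulateConfig", "run", "load_config"]

Stage = Literal["simulate", "segment", "winddrift", "magtransform", "compare", "report"]


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    behavior: Literal["full_drift", "full_compensation", "partial"] = "full_compensation"
    alpha: float = 1.0
    hours: int = 36
    start_lat: float = 41.34
    start_lon: float = -70.60
    start_time: str = "2009-09-14T12:00:00"
    courses: list[tuple[float, float]] = Field(default_factory=lambda: [(0.0, 190.0)])
    forward_speed_kmh: float = 45.0
    airspeed_kmh: float = 40.0
    duty_cycle: bool = False


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    output_dir: str = "natalnav_out"
    seed: int = 0
    earth_radius_km: float = EARTH_RADIUS_KM
    track_csv: str | None = None
    wind_csv: str | None = None
    field: str = "dipole"  # "dipole" or "grid:<path>"
    dipole_b0_nt: float = 30000.0
    dipole_pole_lat: float = 80.0
    dipole_pole_lon: float = -72.0
    nest_lat: float = 41.47
    nest_lon: float = -70.62
    n_breakpoints: int | None = None
    max_breakpoints: int = 4
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)

    def config_hash(self) -> str:
        # output_dir is where results land, not what they are
        payload = self.model_dump()
        payload.pop("output_dir", None)
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def _field_model(config: RunConfig):
    if config.field == "dipole":
        return DipoleModel(
            B0=config.dipole_b0_nt,
            pole=GeoPoint(config.dipole_pole_lat, config.dipole_pole_lon),
        )
    if config.field.startswith("grid:"):
        return ElementGrid.from_csv(config.field[len("grid:"):])
    raise ValueError(f"unknown field model {config.field!r}")


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    header = f"# natalnav {__version__} config={config.config_hash()}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def run(stages: Sequence[Stage], config: RunConfig) -> dict:
    """Execute the requested stages in order; returns the artifact set.

    Stage dependencies are enforced: ``segment`` needs a track (from
    ``simulate`` or ``track_csv``), ``winddrift`` needs segments and a
    wind field, ``magtransform``/``compare`` need a track and field
    model.  A missing dependency raises ``ValueError`` naming it.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    def require(key: str, needed_by: str):
        if key not in artifacts:
            raise ValueError(f"stage '{needed_by}' requires '{key}' from an earlier stage")
        return artifacts[key]

    for stage in stages:
        if stage == "simulate":
            sim = config.simulate
            world = make_world(seed=config.seed)
            manifest = TruthManifest(
                behavior=sim.behavior,
                alpha=sim.alpha,
                courses=[tuple(c) for c in sim.courses],
                forward_speed_kmh=sim.forward_speed_kmh,
                airspeed_kmh=sim.airspeed_kmh,
            )
            start = GeoFix(
                datetime.fromisoformat(sim.start_time),
                GeoPoint(sim.start_lat, sim.start_lon),
            )
            fixes = make_track(world, manifest, start, sim.hours, duty_cycle=sim.duty_cycle)
            artifacts["world"] = world
            artifacts["manifest"] = manifest
            artifacts["track"] = fixes
            df = pd.DataFrame(
                {
                    "timestamp": [f.timestamp.isoformat() for f in fixes],
                    "lat": [f.position.lat for f in fixes],
                    "lon": [f.position.lon for f in fixes],
                }
            )
            _write_csv(df, out_dir / "track.csv", config)
            with open(out_dir / "manifest.json", "w") as fh:
                json.dump(asdict(manifest), fh, indent=2)

        elif stage == "segment":
            if "track" not in artifacts:
                if config.track_csv is None:
                    raise ValueError("stage 'segment' requires a track (simulate or track_csv)")
                artifacts["track"] = read_track_csv(config.track_csv)
            segments = segment_track(
                artifacts["track"],
                n_breakpoints=config.n_breakpoints,
                max_k=config.max_breakpoints,
                earth_radius_km=config.earth_radius_km,
            )
            artifacts["segments"] = segments
            _write_csv(write_summary_table(segments), out_dir / "segments.csv", config)

        elif stage == "winddrift":
            segments = require("segments", "winddrift")
            if "world" in artifacts:
                windfield = artifacts["world"].wind
            elif config.wind_csv is not None:
                windfield = WindField.from_csv(config.wind_csv)
            else:
                raise ValueError("stage 'winddrift' requires a wind field (simulate or wind_csv)")
            steps = []
            for seg in segments:
                steps.extend(
                    decompose_segment(seg.fixes, windfield, seg.summary.direction_deg)
                )
            artifacts["steps"] = steps
            regs = drift_regressions(steps)
            artifacts["drift_regressions"] = regs
            artifacts["overcompensation"] = overcompensation_fraction(steps)
            step_df = pd.DataFrame(
                {
                    "g_speed": [s.g_speed for s in steps],
                    "g_bearing": [s.g_bearing for s in steps],
                    "u10": [s.w.u10 for s in steps],
                    "v10": [s.w.v10 for s in steps],
                    "h_speed": [s.h_speed for s in steps],
                    "h_bearing": [s.h_bearing for s in steps],
                    "delta": [s.delta for s in steps],
                    "p_w": [s.p_w for s in steps],
                    "t_w": [s.t_w for s in steps],
                    "p_m": [s.p_m for s in steps],
                    "f_m": [s.f_m for s in steps],
                    "a_m": [s.a_m for s in steps],
                    "mu": [s.mu for s in steps],
                }
            )
            _write_csv(step_df, out_dir / "steps.csv", config)
            reg_df = pd.DataFrame([asdict(r) for r in regs.values()])
            _write_csv(reg_df, out_dir / "drift_regressions.csv", config)

        elif stage == "magtransform":
            if "track" not in artifacts and config.track_csv is not None:
                artifacts["track"] = read_track_csv(config.track_csv)
            track = require("track", "magtransform")
            field_model = _field_model(config)
            frame = NatalFrame.from_field(
                field_model, GeoPoint(config.nest_lat, config.nest_lon)
            )
            artifacts["natal_frame"] = frame
            rows = []
            for f in track:
                el = field_model.elements(f.position)
                nc = natal_transform((el.X, el.Y, el.Z), frame)
                rows.append(
                    {
                        "timestamp": f.timestamp.isoformat(),
                        "lat": f.position.lat,
                        "lon": f.position.lon,
                        "F": el.F,
                        "I": el.I,
                        "D": el.D,
                        "x_T": nc.x_T,
                        "y_T": nc.y_T,
                        "z_T": nc.z_T,
                    }
                )
            df = pd.DataFrame(rows)
            artifacts["natal_coords"] = df
            _write_csv(df, out_dir / "natal_coords.csv", config)

        elif stage == "compare":
            segments = require("segments", "compare")
            field_model = _field_model(config)
            frame = NatalFrame.from_field(
                field_model, GeoPoint(config.nest_lat, config.nest_lon)
            )
            seg_map = {f"seg{j + 1}": seg.fixes for j, seg in enumerate(segments)}
            frames = {k: frame for k in seg_map}
            results = {}
            for space, model in (
                ("mercator", "linear"),
                ("HZ_cartesian", "poly4"),
                ("yTzT", "linear"),
            ):
                traces = trace_tracks(
                    seg_map, space, field_model=field_model, natal_frames=frames,
                    earth_radius_km=config.earth_radius_km,
                )
                matrix = pairwise_coefficient_tests(traces, model=model)
                results[space] = matrix
                _write_csv(
                    matrix.p_dataframe().reset_index(names="segment_id"),
                    out_dir / f"pairwise_p_{space}.csv",
                    config,
                )
            artifacts["compare"] = results
            yt_traces = trace_tracks(
                seg_map, "yTzT", field_model=field_model, natal_frames=frames
            )
            _write_csv(
                natal_straightness_table(yt_traces), out_dir / "natal_straightness.csv", config
            )

        elif stage == "report":
            seg_tab = fixtures.segment_summaries()
            natal_tab = fixtures.natal_straightness()
            report = {
                "reference_mean_straightness": float(seg_tab["straightness"].mean()),
                "reference_mean_direction_deg": float(seg_tab["direction_deg"].mean()),
                "reference_count_ge_098": int((seg_tab["straightness"] >= 0.98).sum()),
                "reference_count_ge_095": int((seg_tab["straightness"] >= 0.95).sum()),
                "reference_natal_mean_straightness": float(natal_tab["straightness"].mean()),
                "reference_natal_count_gt_095": int((natal_tab["straightness"] > 0.95).sum()),
            }
            if "drift_regressions" in artifacts:
                regs = artifacts["drift_regressions"]
                report["pm_pw_slope"] = regs["pm_pw"].slope
                report["pm_pw_slope_se"] = regs["pm_pw"].slope_se
                report["fm_tw_intercept"] = regs["fm_tw"].intercept
                report["overcompensation_fraction"] = artifacts["overcompensation"]
            if "segments" in artifacts:
                segs = artifacts["segments"]
                report["n_segments"] = len(segs)
                report["mean_straightness"] = float(
                    np.mean([s.summary.straightness for s in segs])
                )
            artifacts["report"] = report
            _write_csv(
                pd.DataFrame([report]).T.reset_index().set_axis(["quantity", "value"], axis=1),
                out_dir / "report.csv",
                config,
            )

        else:
            raise ValueError(f"unknown stage {stage!r}")

    return artifacts
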