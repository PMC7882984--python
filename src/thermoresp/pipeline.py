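"""End-to-end orchestration: simulate -> reduce -> convert -> model -> report.

The pipeline is driven by a validated :class:`PipelineConfig` (YAML
round-trippable).  Every physiological point in the report is traceable to
a session, step index and stable-window interval; every excluded step is
logged with a reason.  All stochastic stages are seeded, so the same
configuration yields a byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import physio, traces
from .models import HeatResponseModel, fold_changes
from .polygon import ThermoPolygon
from .synth import (BirdPopulation, RampProtocol, RespirometrySession,
                    SessionNoise, sample_birds, simulate_session)

log = logging.getLogger(__name__)

#: Report/trait name -> column of the physiological points table.
TRAIT_COLUMNS = {
    "tb": "Tb_C",
    "rmr": "rmr_W",
    "ewl": "ewl_g_per_hr",
    "ehl_mhp": "ehl_mhp",
}


@dataclass
class PipelineConfig:
    """Everything a full run needs, with explicit validation."""

    n_birds: int = 42
    seed: int = 0
    flow_ml_min: float = 2500.0
    chamber_volume_L: float = 2.6
    fio2: float = 0.2095
    protocol: RampProtocol = field(default_factory=RampProtocol)
    noise: SessionNoise = field(default_factory=SessionNoise)
    population: BirdPopulation = field(default_factory=BirdPopulation)
    window_s: int = 300
    grid_C: float = 0.01
    bootstrap_B: int = 0              # >= 200 enables breakpoint CIs
    delta_threshold: float = 8.0
    weight_threshold: float = 0.90
    cooks_threshold: float = 1.0
    fold_low_C: float = 26.0
    fold_high_C: float = 43.0
    fold_half_width_C: float = 1.5
    polygon_bmr_W: float = 0.563
    polygon_conductance_W_per_C: float = 0.1167
    polygon_tb_C: float = 41.3
    activity_multiplier: float = 4.0
    traits: tuple = ("tb", "rmr", "ewl", "ehl_mhp")

    def validate(self):
        if self.n_birds < 1:
            raise ValueError("config field n_birds must be >= 1")
        if self.seed is None:
            raise ValueError("config field seed is required (stochastic stages)")
        for name in ("flow_ml_min", "chamber_volume_L", "grid_C",
                     "delta_threshold", "weight_threshold", "cooks_threshold",
                     "polygon_bmr_W", "polygon_conductance_W_per_C"):
            if getattr(self, name) is None or getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        if not 0 < self.fio2 < 0.21:
            raise ValueError("config field fio2 must lie in (0, 0.21)")
        if self.bootstrap_B not in (0,) and self.bootstrap_B < 200:
            raise ValueError("config field bootstrap_B must be 0 or >= 200")
        unknown = set(self.traits) - set(TRAIT_COLUMNS)
        if unknown:
            raise ValueError(f"unknown traits in config: {sorted(unknown)}")
        self.protocol.validate()
        self.population.validate()
        return self

    def to_yaml(self, path=None):
        payload = dataclasses.asdict(self)
        payload["traits"] = list(self.traits)
        text = yaml.safe_dump(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path):
        payload = yaml.safe_load(Path(path).read_text())
        for key, sub in (("protocol", RampProtocol), ("noise", SessionNoise),
                         ("population", BirdPopulation)):
            if key in payload and isinstance(payload[key], dict):
                payload[key] = sub(**payload[key])
        if "traits" in payload:
            payload["traits"] = tuple(payload["traits"])
        return cls(**payload).validate()


def simulate_study(config):
    """Simulate one session per bird; per-session seeds derive from config.seed."""
    config.validate()
    birds = sample_birds(config.n_birds, config.population, seed=config.seed)
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=config.n_birds)
    return [
        simulate_session(b, config.protocol, config.noise, seed=int(s),
                         flow_ml_min=config.flow_ml_min,
                         chamber_volume_L=config.chamber_volume_L)
        for b, s in zip(birds, seeds)
    ]


def reduce_sessions(sessions, config):
    """Per-step trace summaries -> physiological points for many sessions."""
    tables, exclusions = [], []
    for s in sessions:
        summary, excl = traces.summarize_session(
            s, window_s=config.window_s,
            o2_lag_s=config.noise.o2_lag_s, wvp_lag_s=config.noise.wvp_lag_s,
            o2_reference=config.fio2)
        exclusions.extend(excl)
        if len(summary):
            tables.append(physio.points_from_summary(
                summary, flow_ml_min=s.flow_ml_min, mass_g=s.mass_g,
                rq=s.rq, fio2=config.fio2))
    if not tables:
        return pd.DataFrame(), exclusions
    return pd.concat(tables, ignore_index=True), exclusions


def load_sessions(directory):
    """Read every session CSV (+ JSON sidecar) in a directory."""
    paths = sorted(Path(directory).glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no session CSV files in {directory}")
    return [RespirometrySession.read(p) for p in paths]


def analyze_points(points, config):
    """Per-trait breakpoint + model-selection analysis of a points table."""
    out = {}
    for trait in config.traits:
        col = TRAIT_COLUMNS[trait]
        res = HeatResponseModel(points, col).fit(
            grid=config.grid_C, boot=config.bootstrap_B, seed=config.seed,
            delta_threshold=config.delta_threshold,
            weight_threshold=config.weight_threshold,
            cooks_threshold=config.cooks_threshold)
        entry = res.to_dict()
        entry["column"] = col
        try:
            fc = fold_changes(points, col, low_center=config.fold_low_C,
                              high_center=config.fold_high_C,
                              half_width=config.fold_half_width_C)
            entry["fold_change"] = dataclasses.asdict(fc)
            entry["fold_change"]["ratio"] = fc.ratio_rounded
        except ValueError as exc:
            entry["fold_change"] = None
            log.warning("fold change unavailable for %s: %s", trait, exc)
        out[trait] = entry
    return out


def run_pipeline(config, outdir=None):
    """Execute the full pipeline and return (and optionally write) the report.

    Stages: simulate -> reduce -> convert -> breakpoints -> mixed models ->
    fold changes -> polygon.  With `outdir`, writes ``points.csv`` and
    ``report.json`` (deterministic byte content for a fixed config).
    """
    config.validate()
    sessions = simulate_study(config)
    points, exclusions = reduce_sessions(sessions, config)
    if points.empty:
        raise RuntimeError("no physiological points survived reduction")

    report = {
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=list)),
        "n_birds": int(points["bird_id"].nunique()),
        "n_points": int(len(points)),
        "exclusions": exclusions,
        "traits": analyze_points(points, config),
    }
    scopes = [physio.evaporative_scope(g["ewl_g_per_hr"].to_numpy())
              for _, g in points.groupby("bird_id") if len(g) >= 2]
    report["evaporative_scope_mean"] = float(np.mean(scopes)) if scopes else None
    report["polygon"] = ThermoPolygon(
        config.polygon_bmr_W, config.polygon_conductance_W_per_C,
        config.polygon_tb_C, config.activity_multiplier).to_dict()

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        points.to_csv(outdir / "points.csv", index=False)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True, default=float))
    return report, points
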