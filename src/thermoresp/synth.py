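"""Synthetic ramped-temperature respirometry sessions with known ground truth.

This module generates the raw 1 Hz traces an open flow-through system
records while a small passerine sits in a ventilated metabolic chamber
exposed to a stepped air-temperature (Ta) ramp:

* excurrent O2 fraction and water vapor pressure follow first-order
  (well-mixed, single compartment) washout with time constant
  ``volume / flow`` toward the steady state implied by the bird's true
  physiological state at the current Ta;
* both analyzers drift linearly in time;
* the multiplexer records a baseline (incurrent air) channel for a fixed
  period at the start and end of the run, and the chamber channel in
  between;
* the run terminates as soon as the simulated core body temperature
  reaches the welfare cutoff (default 45 degC).

True trait responses are flat below a trait-specific Ta inflection and
rise linearly above it.  Between-bird variation enters through per-bird
random intercepts and within-bird variation through per-step residual
deviations, mirroring the random-intercept mixed models fitted downstream.
Every per-step true value is retained on the session object so the full
reduction pipeline can be validated against known ground truth.

Default parameter values describe a ~31 g cold-specialist passerine:
body temperature plateau 41.3 degC inflecting at Ta 32.6 degC with slope
0.299 degC/degC, resting metabolic rate plateau 0.588 W inflecting at
29.8 degC with slope 0.014 W/degC, and evaporative water loss baseline
0.315 g/hr inflecting at 34.6 degC with slope 0.068 g/hr/degC.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import physio

#: O2 fraction of the scrubbed (dry, CO2-free) incurrent airstream.
O2_INCURRENT = 0.2095

#: Water vapor pressure of the scrubbed incurrent airstream, kPa.  Silica
#: gel + drierite leave a trace residual (dew point around -24 degC); a
#: strictly positive baseline also keeps a negatively drifting analyzer
#: reading above zero, so the bracketing baselines retain the drift signal.
WVP_INCURRENT = 0.06

TRAITS = ("tb", "rmr", "ewl")

SESSION_COLUMNS = [
    "time_s", "channel", "o2_fraction", "wvp_kPa",
    "Ta_C", "Tb_core_C", "Tb_sub_C",
]


@dataclass
class BirdPopulation:
    """Distribution parameters from which bird parameter sets are drawn.

    Means describe the population-level trait responses; `intercept_sd`
    gives the SD of the per-bird random intercept for each trait and
    `residual_sd` the SD of the per-step residual deviation on the reduced
    trait scale.  Breakpoints (`psi_*`) are population constants by default
    (`psi_sd_C = 0`), matching a pooled-breakpoint analysis.
    """

    mass_mean_g: float = 31.0
    mass_sd_g: float = 2.1
    tb_base_C: float = 41.3
    bmr_W: float = 0.588  # resting plateau below the RMR inflection
    ewl_base_g_per_hr: float = 0.315
    psi_tb_C: float = 32.6
    psi_rmr_C: float = 29.8
    psi_ewl_C: float = 34.6
    psi_sd_C: float = 0.0
    slope_tb_C_per_C: float = 0.299
    slope_rmr_W_per_C: float = 0.014
    slope_ewl_g_per_hr_per_C: float = 0.068
    intercept_sd: dict = field(
        default_factory=lambda: {"tb": 0.15, "rmr": 0.08, "ewl": 0.05})
    residual_sd: dict = field(
        default_factory=lambda: {"tb": 0.15, "rmr": 0.05, "ewl": 0.04})
    conductance_W_per_C: float = 0.1167
    fasted_mean_min: float = 90.0
    fasted_sd_min: float = 25.0
    fasted_threshold_min: float = 62.0

    def validate(self):
        for name in ("mass_sd_g", "psi_sd_C", "fasted_sd_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for d in (self.intercept_sd, self.residual_sd):
            for trait, sd in d.items():
                if trait not in TRAITS:
                    raise ValueError(f"unknown trait {trait!r}")
                if sd < 0:
                    raise ValueError(f"negative SD for trait {trait!r}")
        if self.mass_mean_g <= 0 or self.bmr_W <= 0:
            raise ValueError("mass and BMR must be positive")


@dataclass
class BirdParams:
    """Realized parameter set for one bird (ground truth of a session)."""

    bird_id: str
    mass_g: float
    bmr_W: float
    conductance_W_per_C: float
    tb_base_C: float
    ewl_base_g_per_hr: float
    psi_tb_C: float
    psi_rmr_C: float
    psi_ewl_C: float
    slope_tb_C_per_C: float
    slope_rmr_W_per_C: float
    slope_ewl_g_per_hr_per_C: float
    residual_sd: dict
    random_intercept_sd: dict
    rq: float
    fasted_min: float

    def validate(self):
        if self.mass_g <= 0 or self.bmr_W <= 0 or self.conductance_W_per_C <= 0:
            raise ValueError("mass, BMR and conductance must be positive")
        for name in ("slope_tb_C_per_C", "slope_rmr_W_per_C",
                     "slope_ewl_g_per_hr_per_C"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.7 <= self.rq <= 1.0:
            raise ValueError("RQ must lie in [0.7, 1.0]")
        if self.fasted_min < 0:
            raise ValueError("fasting time cannot be negative")


def sample_birds(n, population=None, seed=None):
    """Draw `n` bird parameter sets from a :class:`BirdPopulation`.

    Reproducible for a fixed seed; with all SDs zero the returned
    parameters equal the configured means exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pop = population or BirdPopulation()
    pop.validate()
    rng = np.random.default_rng(seed)
    birds = []
    for i in range(n):
        mass = pop.mass_mean_g + (rng.normal(0, pop.mass_sd_g) if pop.mass_sd_g else 0.0)
        icpt = {t: (rng.normal(0, pop.intercept_sd[t]) if pop.intercept_sd[t] else 0.0)
                for t in TRAITS}
        psi = {t: getattr(pop, f"psi_{t}_C")
               + (rng.normal(0, pop.psi_sd_C) if pop.psi_sd_C else 0.0)
               for t in TRAITS}
        fasted = max(0.0, pop.fasted_mean_min
                     + (rng.normal(0, pop.fasted_sd_min) if pop.fasted_sd_min else 0.0))
        b = BirdParams(
            bird_id=f"bird{i:03d}",
            mass_g=max(mass, 1.0),
            bmr_W=max(pop.bmr_W + icpt["rmr"], 1e-3),
            conductance_W_per_C=pop.conductance_W_per_C,
            tb_base_C=pop.tb_base_C + icpt["tb"],
            ewl_base_g_per_hr=max(pop.ewl_base_g_per_hr + icpt["ewl"], 1e-4),
            psi_tb_C=psi["tb"],
            psi_rmr_C=psi["rmr"],
            psi_ewl_C=psi["ewl"],
            slope_tb_C_per_C=pop.slope_tb_C_per_C,
            slope_rmr_W_per_C=pop.slope_rmr_W_per_C,
            slope_ewl_g_per_hr_per_C=pop.slope_ewl_g_per_hr_per_C,
            residual_sd=dict(pop.residual_sd),
            random_intercept_sd=dict(pop.intercept_sd),
            rq=physio.select_rq(fasted, threshold_min=pop.fasted_threshold_min),
            fasted_min=fasted,
        )
        b.validate()
        birds.append(b)
    return birds


def true_response(params, Ta, trait):
    """Noise-free trait value at air temperature `Ta`.

    Flat at the trait baseline for Ta at or below the trait's inflection
    psi, rising linearly with the trait slope above it.  `trait` is one of
    ``"tb"``, ``"rmr"``, ``"ewl"``; ``"ehl_mhp"`` is accepted as a derived
    convenience (EHL from the EWL response divided by the RMR response).
    """
    ta = np.asarray(Ta, dtype=float)
    if trait == "tb":
        base, psi, slope = params.tb_base_C, params.psi_tb_C, params.slope_tb_C_per_C
    elif trait == "rmr":
        base, psi, slope = params.bmr_W, params.psi_rmr_C, params.slope_rmr_W_per_C
    elif trait == "ewl":
        base, psi, slope = (params.ewl_base_g_per_hr, params.psi_ewl_C,
                            params.slope_ewl_g_per_hr_per_C)
    elif trait == "ehl_mhp":
        ehl = physio.ehl_watts(true_response(params, ta, "ewl"))
        return physio.efficiency(ehl, true_response(params, ta, "rmr"))
    else:
        raise ValueError(f"unknown trait {trait!r}")
    val = base + slope * np.clip(ta - psi, 0.0, None)
    return float(val) if np.ndim(Ta) == 0 else val


@dataclass
class RampProtocol:
    """Stepped Ta profile of one respirometry run."""

    start_Ta_C: float = 25.0
    end_Ta_C: float = 43.0
    step_C: float = 2.0
    step_minutes: float = 15.0
    habituation_minutes: float = 30.0
    baseline_minutes: float = 10.0
    max_Tb_C: float = 45.0

    def validate(self):
        if self.step_C <= 0:
            raise ValueError("step_C must be positive")
        if self.step_minutes < 10:
            raise ValueError("step_minutes must be >= 10")
        if self.end_Ta_C < self.start_Ta_C:
            raise ValueError("end_Ta_C must be >= start_Ta_C")
        if self.baseline_minutes <= 0 or self.habituation_minutes < 0:
            raise ValueError("baseline/habituation durations invalid")

    def ta_levels(self):
        return np.arange(self.start_Ta_C, self.end_Ta_C + self.step_C / 2,
                         self.step_C)


@dataclass
class SessionNoise:
    """Measurement noise, analyzer drift, lag and secondary-sensor config."""

    o2_sd: float = 5e-6
    wvp_sd_kPa: float = 0.002
    ta_sd_C: float = 0.05
    tb_sd_C: float = 0.05
    o2_drift_per_hr: float = 0.0
    o2_drift_per_hr_sd: float = 1e-4
    wvp_drift_per_hr_kPa: float = 0.0
    wvp_drift_per_hr_sd_kPa: float = 0.01
    tb_sub_offset_C: float = 0.2
    tb_sub_sd_C: float = 0.1
    o2_lag_s: int = 12
    wvp_lag_s: int = 20

    @classmethod
    def zero(cls):
        """No stochastic noise or drift; lags and the sub-cutaneous sensor
        offset are kept (they are deterministic and correctable)."""
        return cls(o2_sd=0.0, wvp_sd_kPa=0.0, ta_sd_C=0.0, tb_sd_C=0.0,
                   o2_drift_per_hr=0.0, o2_drift_per_hr_sd=0.0,
                   wvp_drift_per_hr_kPa=0.0, wvp_drift_per_hr_sd_kPa=0.0,
                   tb_sub_sd_C=0.0)

    def stochastic(self):
        return any(v > 0 for v in (
            self.o2_sd, self.wvp_sd_kPa, self.ta_sd_C, self.tb_sd_C,
            self.o2_drift_per_hr_sd, self.wvp_drift_per_hr_sd_kPa,
            self.tb_sub_sd_C))


@dataclass
class RespirometrySession:
    """Raw multiplexed 1 Hz traces plus metadata and retained ground truth."""

    bird_id: str
    data: pd.DataFrame
    steps: pd.DataFrame
    mass_g: float
    flow_ml_min: float
    chamber_volume_L: float
    fasted_min: float
    rq: float
    seed: object
    truth: dict

    def write(self, directory):
        """Write the trace CSV and a JSON sidecar; returns the two paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        csv_path = directory / f"{self.bird_id}.csv"
        json_path = directory / f"{self.bird_id}.json"
        self.data.to_csv(csv_path, index=False)
        sidecar = {
            "bird_id": self.bird_id,
            "mass_g": self.mass_g,
            "flow_ml_min": self.flow_ml_min,
            "chamber_volume_L": self.chamber_volume_L,
            "fasted_min": self.fasted_min,
            "rq": self.rq,
            "seed": self.seed,
            "steps": self.steps.to_dict(orient="list"),
            "truth": self.truth,
        }
        json_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
        return csv_path, json_path

    @classmethod
    def read(cls, csv_path):
        csv_path = Path(csv_path)
        sidecar = json.loads(csv_path.with_suffix(".json").read_text())
        return cls(
            bird_id=sidecar["bird_id"],
            data=pd.read_csv(csv_path),
            steps=pd.DataFrame(sidecar["steps"]),
            mass_g=sidecar["mass_g"],
            flow_ml_min=sidecar["flow_ml_min"],
            chamber_volume_L=sidecar["chamber_volume_L"],
            fasted_min=sidecar["fasted_min"],
            rq=sidecar["rq"],
            seed=sidecar["seed"],
            truth=sidecar["truth"],
        )


def _lag_shift(values, lag):
    """Delay a signal by `lag` samples (analyzer response latency)."""
    lag = int(lag)
    if lag <= 0:
        return values
    return np.concatenate([np.full(lag, values[0]), values[:-lag]])


def simulate_session(params, protocol=None, noise=None, seed=None,
                     flow_ml_min=2500.0, chamber_volume_L=2.6):
    """Simulate one full respirometry run for one bird.

    Parameters
    ----------
    params : BirdParams
        Ground-truth parameters (see :func:`sample_birds`).
    protocol : RampProtocol, optional
    noise : SessionNoise, optional
    seed : int, optional
        Required whenever any stochastic component (noise, drift, per-step
        residuals) is active.
    flow_ml_min, chamber_volume_L : float
        Chamber setup; the washout time constant is ``volume / flow``.

    Returns
    -------
    RespirometrySession
    """
    protocol = protocol or RampProtocol()
    protocol.validate()
    params.validate()
    noise = noise or SessionNoise()
    if flow_ml_min <= 0 or chamber_volume_L <= 0:
        raise ValueError("flow and chamber volume must be positive")
    stochastic = noise.stochastic() or any(
        params.residual_sd.get(t, 0.0) > 0 for t in TRAITS)
    if stochastic and seed is None:
        raise ValueError("seed is required when noise, drift or residual "
                         "variation is enabled")
    rng = np.random.default_rng(0 if seed is None else seed)

    def _norm(sd, size=None):
        if sd <= 0:
            return 0.0 if size is None else np.zeros(size)
        return rng.normal(0.0, sd, size)

    o2_drift_s = (noise.o2_drift_per_hr + _norm(noise.o2_drift_per_hr_sd)) / 3600.0
    wvp_drift_s = (noise.wvp_drift_per_hr_kPa
                   + _norm(noise.wvp_drift_per_hr_sd_kPa)) / 3600.0

    tau_s = chamber_volume_L / (flow_ml_min / 1000.0) * 60.0
    oj = physio.oxyjoule_J_per_ml(params.rq)
    flow_m3_hr = flow_ml_min * 60.0 / 1e6

    levels = protocol.ta_levels()
    base_s = int(round(protocol.baseline_minutes * 60))
    hab_s = int(round(protocol.habituation_minutes * 60))
    step_s = int(round(protocol.step_minutes * 60))

    segments = [("baseline", -1, float(levels[0]), base_s)]
    if hab_s > 0:
        segments.append(("habituation", -1, float(levels[0]), hab_s))
    segments += [("step", k, float(ta), step_s) for k, ta in enumerate(levels)]

    chunks = []          # per-segment dicts of arrays
    step_records = []
    state_o2, state_wvp = O2_INCURRENT, WVP_INCURRENT
    t0 = 0
    truncated = False

    def _chamber_targets(Ta):
        eps = {t: _norm(params.residual_sd.get(t, 0.0)) for t in TRAITS}
        tb = true_response(params, Ta, "tb") + eps["tb"]
        rmr = max(true_response(params, Ta, "rmr") + eps["rmr"], 1e-3)
        ewl = max(true_response(params, Ta, "ewl") + eps["ewl"], 0.0)
        vo2 = rmr * 60.0 / oj
        feo2 = O2_INCURRENT - vo2 * (1.0 - O2_INCURRENT) / flow_ml_min
        wvp_ss = WVP_INCURRENT + physio.wvp_from_density_kPa(ewl / flow_m3_hr, Ta)
        return tb, rmr, ewl, feo2, wvp_ss

    for phase, k, ta_set, dur in segments:
        tb_t, rmr_t, ewl_t, feo2_ss, wvp_ss = _chamber_targets(ta_set)
        t_rel = np.arange(1, dur + 1, dtype=float)
        decay = np.exp(-t_rel / tau_s)
        o2_ch = feo2_ss + (state_o2 - feo2_ss) * decay
        wvp_ch = wvp_ss + (state_wvp - wvp_ss) * decay
        tb_core = tb_t + _norm(noise.tb_sd_C, dur)

        n_keep = dur
        if phase != "baseline":
            hot = np.flatnonzero(tb_core >= protocol.max_Tb_C)
            if hot.size:
                n_keep = int(hot[0]) + 1
                truncated = True
        state_o2 = o2_ch[n_keep - 1] if n_keep else state_o2
        state_wvp = wvp_ch[n_keep - 1] if n_keep else state_wvp

        chunks.append({
            "time_s": t0 + np.arange(n_keep),
            "channel": np.full(n_keep, "baseline" if phase == "baseline" else "chamber"),
            "o2_gas": (np.full(n_keep, O2_INCURRENT) if phase == "baseline"
                       else o2_ch[:n_keep]),
            "wvp_gas": (np.full(n_keep, WVP_INCURRENT) if phase == "baseline"
                        else wvp_ch[:n_keep]),
            "Ta_set": np.full(n_keep, ta_set),
            "Tb_core": tb_core[:n_keep],
        })
        if phase == "step":
            step_records.append({
                "step_index": k, "Ta_set_C": ta_set,
                "start_s": t0, "end_s": t0 + n_keep,
                "completed": bool(n_keep == dur),
                "tb_true": tb_t, "rmr_true": rmr_t, "ewl_true": ewl_t,
                "ehl_mhp_true": physio.efficiency(physio.ehl_watts(ewl_t), rmr_t),
            })
        t0 += n_keep
        if truncated:
            break

    # closing baseline (recorded even after a welfare truncation)
    tb_end = chunks[-1]["Tb_core"][-1] if len(chunks[-1]["Tb_core"]) else 41.3
    chunks.append({
        "time_s": t0 + np.arange(base_s),
        "channel": np.full(base_s, "baseline"),
        "o2_gas": np.full(base_s, O2_INCURRENT),
        "wvp_gas": np.full(base_s, WVP_INCURRENT),
        "Ta_set": np.full(base_s, chunks[-1]["Ta_set"][-1]),
        "Tb_core": np.full(base_s, float(tb_end)),
    })

    time_s = np.concatenate([c["time_s"] for c in chunks]).astype(float)
    channel = np.concatenate([c["channel"] for c in chunks])
    o2_gas = np.concatenate([c["o2_gas"] for c in chunks])
    wvp_gas = np.concatenate([c["wvp_gas"] for c in chunks])
    ta_set = np.concatenate([c["Ta_set"] for c in chunks])
    tb_core = np.concatenate([c["Tb_core"] for c in chunks])
    n = time_s.size

    o2_meas = _lag_shift(o2_gas, noise.o2_lag_s) + o2_drift_s * time_s \
        + _norm(noise.o2_sd, n)
    wvp_meas = _lag_shift(wvp_gas, noise.wvp_lag_s) + wvp_drift_s * time_s \
        + _norm(noise.wvp_sd_kPa, n)
    wvp_meas = np.clip(wvp_meas, 0.0, None)
    ta_meas = ta_set + _norm(noise.ta_sd_C, n)
    tb_sub = tb_core - noise.tb_sub_offset_C + _norm(noise.tb_sub_sd_C, n)

    data = pd.DataFrame({
        "time_s": time_s, "channel": channel, "o2_fraction": o2_meas,
        "wvp_kPa": wvp_meas, "Ta_C": ta_meas, "Tb_core_C": tb_core,
        "Tb_sub_C": tb_sub,
    })
    steps = pd.DataFrame(step_records, columns=[
        "step_index", "Ta_set_C", "start_s", "end_s", "completed",
        "tb_true", "rmr_true", "ewl_true", "ehl_mhp_true"])
    truth = {
        "o2_drift_per_s": float(o2_drift_s),
        "wvp_drift_per_s_kPa": float(wvp_drift_s),
        "panting_onset_Ta_C": params.psi_ewl_C - 1.4,
        "truncated": truncated,
        "params": dataclasses.asdict(params),
    }
    return RespirometrySession(
        bird_id=params.bird_id, data=data, steps=steps, mass_g=params.mass_g,
        flow_ml_min=flow_ml_min, chamber_volume_L=chamber_volume_L,
        fasted_min=params.fasted_min, rq=params.rq,
        seed=None if seed is None else int(seed), truth=truth,
    )
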