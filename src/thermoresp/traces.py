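"""Reduction of raw multiplexed traces to per-step resting values.

Lag alignment, baseline drift correction, stable-window selection and
per-step summarization.  "Stability" is defined as the minimum sample
variance of the O2 trace over a sliding 5-min window (1 s stride),
earliest window winning ties.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

LN20 = math.log(20.0)


def washout_t95(volume_L, flow_ml_min):
    """Minutes for a well-mixed chamber to reach 95% of a new steady state.

    t95 = (volume / flow) * ln(20) for first-order washout.
    """
    if volume_L <= 0 or flow_ml_min <= 0:
        raise ValueError("volume and flow must be positive")
    return volume_L / (flow_ml_min / 1000.0) * LN20


def sensor_agreement(core, reference):
    """Mean and sample SD of absolute deviations between paired Tb sensors."""
    core = np.asarray(core, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if core.shape != ref.shape or core.size < 2:
        raise ValueError("need at least two paired readings")
    dev = np.abs(core - ref)
    return float(dev.mean()), float(dev.std(ddof=1))


def baseline_segments(time_s, channel):
    """Contiguous (start_s, end_s) intervals where channel == 'baseline'."""
    mask = np.asarray(channel) == "baseline"
    if not mask.any():
        return []
    edges = np.flatnonzero(np.diff(mask.astype(int)))
    starts = [0] if mask[0] else []
    starts += [int(e) + 1 for e in edges if not mask[e]]
    ends = [int(e) + 1 for e in edges if mask[e]]
    if mask[-1]:
        ends.append(mask.size)
    t = np.asarray(time_s, dtype=float)
    return [(float(t[s]), float(t[e - 1]) + 1.0) for s, e in zip(starts, ends)]


def correct_drift(time_s, values, segments, reference, trim_s=0.0):
    """Remove linear analyzer drift anchored on bracketing baselines.

    The mean reading of the first and last baseline segment is taken at the
    segment centers; the line through (center, mean - reference) is
    subtracted from the whole trace so both baselines read `reference`.
    Exact for affine drift and idempotent on corrected traces.
    """
    if len(segments) < 2:
        raise ValueError("drift correction needs baseline segments at both "
                         "the start and the end of the run")
    t = np.asarray(time_s, dtype=float)
    v = np.asarray(values, dtype=float)
    anchors = []
    for s, e in (segments[0], segments[-1]):
        mask = (t >= s + trim_s) & (t < e)
        if not mask.any():
            raise ValueError("baseline segment empty after trimming")
        anchors.append((0.5 * (s + trim_s + e), v[mask].mean()))
    (t1, m1), (t2, m2) = anchors
    if t2 <= t1:
        raise ValueError("baseline segments must be ordered in time")
    drift = (m1 - reference) + (m2 - m1) / (t2 - t1) * (t - t1)
    return v - drift


def sliding_variance(values, window):
    """Sample variance over every contiguous window (cumulative-sum trick)."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if window > n:
        raise ValueError("window longer than trace")
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    s1 = c1[window:] - c1[:-window]
    s2 = c2[window:] - c2[:-window]
    return np.clip(s2 / window - (s1 / window) ** 2, 0.0, None)


@dataclass
class StableWindow:
    """Most stable 5-min window of one chamber-channel Ta step."""

    step_index: int
    start_s: float
    end_s: float
    mean_o2_fraction: float
    mean_wvp_kPa: float
    mean_Ta_C: float
    mean_Tb_C: float
    variance_metric: float


def find_stable_window(o2, window_s=300):
    """Start index of the minimum-variance window of the O2 trace.

    Ties (to within floating tolerance) go to the earliest window.  Raises
    ValueError if the step holds less than `window_s` seconds of data, in
    which case the caller should flag the step excluded.
    """
    o2 = np.asarray(o2, dtype=float)
    if o2.size < window_s:
        raise ValueError(
            f"step holds {o2.size} s of chamber data; {window_s} s required")
    var = sliding_variance(o2, int(window_s))
    vmin = var.min()
    tol = 1e-9 * max(vmin, 1e-30)
    start = int(np.flatnonzero(var <= vmin + tol)[0])
    return start, float(var[start])


def summarize_session(session, window_s=300, o2_lag_s=None, wvp_lag_s=None,
                      o2_reference=None, wvp_reference=None,
                      baseline_trim_s=60.0, washout_skip_s=None):
    """Reduce a session to one record per retained Ta step.

    Applies analyzer lag alignment, corrects both gas traces for linear
    drift against the bracketing baselines, then computes stable-window
    means per step.  The first `washout_skip_s` seconds of each step are
    never searched (by default the chamber's own 95% equilibration time,
    ``washout_t95(volume, flow)``) — measurements begin once the chamber
    has stabilized after a temperature step, so the equilibration
    transient must not leak into step means.  Steps that were cut short by
    the welfare truncation or hold less than `window_s` seconds of
    post-washout chamber data are excluded (the calm-for-5-min rule).

    Returns
    -------
    (pandas.DataFrame, list of dict)
        Per-step summary and the exclusion log.
    """
    from .synth import O2_INCURRENT, WVP_INCURRENT, SessionNoise

    defaults = SessionNoise()
    o2_lag_s = defaults.o2_lag_s if o2_lag_s is None else o2_lag_s
    wvp_lag_s = defaults.wvp_lag_s if wvp_lag_s is None else wvp_lag_s
    o2_reference = O2_INCURRENT if o2_reference is None else o2_reference
    wvp_reference = WVP_INCURRENT if wvp_reference is None else wvp_reference
    if washout_skip_s is None:
        washout_skip_s = math.ceil(60.0 * washout_t95(
            session.chamber_volume_L, session.flow_ml_min))

    d = session.data
    t = d["time_s"].to_numpy(float)
    channel = d["channel"].to_numpy()
    o2 = d["o2_fraction"].to_numpy(float)
    wvp = d["wvp_kPa"].to_numpy(float)
    ta = d["Ta_C"].to_numpy(float)
    tb = d["Tb_core_C"].to_numpy(float)

    # undo analyzer latency: the reading at t reflects the gas at t - lag
    def _align(x, lag):
        lag = int(lag)
        if lag <= 0:
            return x
        return np.concatenate([x[lag:], np.full(lag, x[-1])])

    o2 = _align(o2, o2_lag_s)
    wvp = _align(wvp, wvp_lag_s)

    segs = baseline_segments(t, channel)
    o2 = correct_drift(t, o2, segs, o2_reference, trim_s=baseline_trim_s)
    wvp = correct_drift(t, wvp, segs, wvp_reference, trim_s=baseline_trim_s)

    records, exclusions = [], []
    for row in session.steps.itertuples(index=False):
        if not row.completed:
            exclusions.append({"bird_id": session.bird_id,
                               "step_index": int(row.step_index),
                               "reason": "truncated (Tb cutoff)"})
            continue
        mask = (t >= row.start_s + washout_skip_s) & (t < row.end_s) \
            & (channel == "chamber")
        idx = np.flatnonzero(mask)
        if idx.size < window_s:
            exclusions.append({"bird_id": session.bird_id,
                               "step_index": int(row.step_index),
                               "reason": f"<{window_s}s of calm chamber data"})
            continue
        start, var = find_stable_window(o2[idx], window_s)
        win = idx[start:start + window_s]
        records.append({
            "bird_id": session.bird_id,
            "step_index": int(row.step_index),
            "Ta_C": float(ta[win].mean()),
            "o2_fraction": float(o2[win].mean()),
            "wvp_kPa": float(wvp[win].mean() - wvp_reference),
            "Tb_C": float(tb[win].mean()),
            "window_start_s": float(t[win[0]]),
            "window_end_s": float(t[win[-1]]) + 1.0,
            "o2_variance": var,
        })
    if not records:
        log.warning("session %s produced no retained steps", session.bird_id)
    cols = ["bird_id", "step_index", "Ta_C", "o2_fraction", "wvp_kPa",
            "Tb_C", "window_start_s", "window_end_s", "o2_variance"]
    return pd.DataFrame(records, columns=cols), exclusions
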