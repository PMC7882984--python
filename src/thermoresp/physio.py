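"""Conversions from respirometry trace means to physiological rates.

Standard open flow-through respirometry bookkeeping (Lighton 2008
conventions): oxygen consumption from fractional O2 depletion of a dry,
CO2-free airstream, metabolic power via the thermal equivalent of oxygen,
evaporative water loss from water vapor pressure and flow, and evaporative
heat loss at the latent heat of vaporization.
"""

from __future__ import annotations

import numpy as np

#: Specific gas constant of water vapor, J kg^-1 K^-1.
R_WATER_VAPOR = 461.5

#: Latent heat of vaporization of water, J per mg H2O.
LATENT_HEAT_J_PER_MG = 2.406

# Thermal equivalent of oxygen, J per ml O2, as a linear function of the
# respiratory quotient: 16 + 5.164 * RQ (Lighton 2008, eq. 9.13 form).
OXYJOULE_INTERCEPT = 16.0
OXYJOULE_SLOPE = 5.164


def _maybe_scalar(x, arr):
    out = np.asarray(arr, dtype=float)
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


def vo2_ml_min(flow_ml_min, fio2, feo2):
    """Oxygen consumption (ml O2/min) of a dry, CO2-free excurrent stream.

    VO2 = FR * (FiO2 - FeO2) / (1 - FiO2), with FR the incurrent flow rate.

    Raises
    ------
    ValueError
        If FeO2 exceeds FiO2 (apparent negative uptake) or fractions are
        outside (0, 1).
    """
    flow = np.asarray(flow_ml_min, dtype=float)
    fi = np.asarray(fio2, dtype=float)
    fe = np.asarray(feo2, dtype=float)
    if np.any(flow <= 0):
        raise ValueError("flow_ml_min must be positive")
    if np.any((fi <= 0) | (fi >= 1)) or np.any(fe <= 0):
        raise ValueError("O2 fractions must lie in (0, 1)")
    if np.any(fe > fi + 1e-12):
        raise ValueError(
            "excurrent O2 fraction exceeds incurrent (negative uptake); "
            "check channel assignment and drift correction"
        )
    return _maybe_scalar(feo2, flow * (fi - fe) / (1.0 - fi))


def oxyjoule_J_per_ml(rq):
    """Thermal equivalent of oxygen (J/ml O2) at respiratory quotient `rq`.

    Valid for 0.7 <= RQ <= 1.0; out-of-range values are refused rather than
    clamped, since they signal an upstream bookkeeping error.
    """
    rq_arr = np.asarray(rq, dtype=float)
    if np.any((rq_arr < 0.7) | (rq_arr > 1.0)):
        raise ValueError(f"RQ must lie in [0.7, 1.0], got {rq!r}")
    return _maybe_scalar(rq, OXYJOULE_INTERCEPT + OXYJOULE_SLOPE * rq_arr)


def select_rq(fasted_min, threshold_min=62.0, rq_fasted=0.71, rq_fed=0.80):
    """Respiratory quotient implied by fasting time.

    Birds fasted for more than `threshold_min` minutes (the mean digesta
    retention time of a ~31 g passerine) are assumed post-absorptive
    (RQ = 0.71, lipid metabolism); otherwise RQ = 0.80.  The threshold is
    exclusive: exactly `threshold_min` minutes still counts as fed.
    """
    if fasted_min < 0:
        raise ValueError("fasting time cannot be negative")
    return rq_fasted if fasted_min > threshold_min else rq_fed


def rmr_watts(vo2, oxyjoule):
    """Metabolic power (W) from VO2 (ml/min) and its thermal equivalent (J/ml)."""
    v = np.asarray(vo2, dtype=float)
    oj = np.asarray(oxyjoule, dtype=float)
    if np.any(v < 0) or np.any(oj <= 0):
        raise ValueError("vo2 must be >= 0 and oxyjoule > 0")
    return _maybe_scalar(vo2, v * oj / 60.0)


def vapor_density_g_m3(wvp_kPa, T_C):
    """Water vapor density (g/m^3) from vapor pressure (kPa) at air temperature T (degC).

    Ideal-gas conversion: rho = e / (Rv * T), evaluated at the chamber air
    temperature (the convention used throughout this package).
    """
    wvp = np.asarray(wvp_kPa, dtype=float)
    t = np.asarray(T_C, dtype=float)
    if np.any(wvp < 0):
        raise ValueError("water vapor pressure cannot be negative")
    if np.any(t < -90) or np.any(t > 90):
        raise ValueError("air temperature outside plausible range")
    return _maybe_scalar(wvp_kPa, wvp * 1e6 / (R_WATER_VAPOR * (t + 273.15)))


def wvp_from_density_kPa(density_g_m3, T_C):
    """Inverse of :func:`vapor_density_g_m3` (used by the simulator)."""
    rho = np.asarray(density_g_m3, dtype=float)
    t = np.asarray(T_C, dtype=float)
    return _maybe_scalar(density_g_m3, rho * R_WATER_VAPOR * (t + 273.15) / 1e6)


def saturation_vapor_pressure_kPa(T_C):
    """Saturation vapor pressure over water (kPa), Tetens' formula."""
    t = np.asarray(T_C, dtype=float)
    return _maybe_scalar(T_C, 0.61078 * np.exp(17.27 * t / (t + 237.3)))


def ewl_g_per_hr(wvp_kPa, T_C, flow_ml_min):
    """Evaporative water loss (g/hr) from chamber WVP and incurrent flow.

    Vapor density (at chamber air temperature) times flow expressed in
    m^3/hr.  `wvp_kPa` should already be baseline/drift corrected so it
    represents water added by the animal.
    """
    flow = np.asarray(flow_ml_min, dtype=float)
    if np.any(flow <= 0):
        raise ValueError("flow_ml_min must be positive")
    flow_m3_hr = flow * 60.0 / 1e6
    return _maybe_scalar(wvp_kPa, vapor_density_g_m3(wvp_kPa, T_C) * flow_m3_hr)


def ehl_watts(ewl_g_hr):
    """Evaporative heat loss (W) from EWL (g/hr) at 2.406 J/mg H2O."""
    e = np.asarray(ewl_g_hr, dtype=float)
    if np.any(e < 0):
        raise ValueError("EWL cannot be negative")
    return _maybe_scalar(ewl_g_hr, e * 1000.0 * LATENT_HEAT_J_PER_MG / 3600.0)


def efficiency(ehl_W, rmr_W):
    """Evaporative cooling efficiency EHL/MHP (dimensionless)."""
    r = np.asarray(rmr_W, dtype=float)
    if np.any(r <= 0):
        raise ValueError("metabolic heat production must be positive")
    return _maybe_scalar(ehl_W, np.asarray(ehl_W, dtype=float) / r)


def evaporative_scope(ewl_values):
    """Ratio of an individual's maximum to minimum EWL across Ta steps."""
    e = np.asarray(ewl_values, dtype=float)
    if e.size < 2:
        raise ValueError("evaporative scope needs at least two observations")
    if e.min() <= 0:
        raise ValueError("minimum EWL must be positive")
    return float(e.max() / e.min())


def points_from_summary(summary, flow_ml_min, mass_g, fasted_min=None, rq=None,
                        fio2=0.2095, threshold_min=62.0):
    """Convert a per-step trace summary into a table of physiological points.

    Parameters
    ----------
    summary : pandas.DataFrame
        Output of :func:`thermoresp.traces.summarize_session` (one row per
        retained Ta step, with drift-corrected `o2_fraction` and `wvp_kPa`
        column means).
    flow_ml_min, mass_g : float
        Incurrent flow rate and body mass before measurement.
    fasted_min, rq : float, optional
        Either an explicit RQ or a fasting time from which it is selected.
    fio2 : float
        Incurrent O2 fraction of the scrubbed airstream.

    Returns
    -------
    pandas.DataFrame
        One row per bird x Ta step with columns Ta_C, Tb_C, rmr_W,
        ewl_g_per_hr, ehl_W, ehl_mhp, mass_g, rq_used plus traceability
        columns carried over from the summary.
    """
    out = summary.copy()
    if rq is None:
        if fasted_min is None:
            raise ValueError("provide either rq or fasted_min")
        rq = select_rq(fasted_min, threshold_min=threshold_min)
    vo2 = vo2_ml_min(flow_ml_min, fio2, out["o2_fraction"].to_numpy())
    out["rmr_W"] = rmr_watts(vo2, oxyjoule_J_per_ml(rq))
    out["ewl_g_per_hr"] = ewl_g_per_hr(
        out["wvp_kPa"].to_numpy(), out["Ta_C"].to_numpy(), flow_ml_min
    )
    out["ehl_W"] = ehl_watts(out["ewl_g_per_hr"].to_numpy())
    out["ehl_mhp"] = efficiency(out["ehl_W"].to_numpy(), out["rmr_W"].to_numpy())
    out["mass_g"] = float(mass_g)
    out["rq_used"] = float(rq)
    return out
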