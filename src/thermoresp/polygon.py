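"""Thermoregulatory polygon: passive heat-balance limits for an endotherm.

The dry heat-dissipation boundary M = C * (Tb - Ta) (metabolic heat that
can be lost without evaporation at body-to-air gradient Tb - Ta and
thermal conductance C), together with a metabolic floor at BMR and a
ceiling at an activity multiple of BMR, bounds the region of (Ta, M)
space where body temperature can be held constant without evaporative
cooling or hyperthermia (Rezende & Bacigalupe 2015 framework).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

#: Default dry thermal conductance, W/degC.  Not an independently measured
#: value: it is back-computed from a passive limit of 22 degC at 4x a BMR
#: of 0.563 W with Tb 41.3 degC, i.e. C = 4*0.563/(41.3-22).  Supply a
#: measured conductance whenever one is available.
DEFAULT_CONDUCTANCE_W_PER_C = 0.1167


def passive_limit(bmr_W, conductance_W_per_C, tb_C, multiplier=4.0):
    """Maximum Ta (degC) permitting passive balance at `multiplier` x BMR.

    Ta_max = Tb - multiplier * BMR / C, the intersection of the metabolic
    ceiling with the dry dissipation line.
    """
    if bmr_W <= 0 or conductance_W_per_C <= 0:
        raise ValueError("BMR and conductance must be positive")
    if multiplier < 1:
        raise ValueError("activity multiplier must be >= 1")
    ta = tb_C - multiplier * bmr_W / conductance_W_per_C
    if ta < -100.0:
        warnings.warn(f"passive limit {ta:.1f} degC is implausibly low; "
                      "check conductance units", stacklevel=2)
    return ta


def conductance_from_limit(ta_max_C, tb_C, bmr_W, multiplier=4.0):
    """Conductance implied by an observed passive limit (inverse relation)."""
    if tb_C <= ta_max_C:
        raise ValueError("passive limit must lie below body temperature")
    return multiplier * bmr_W / (tb_C - ta_max_C)


def polygon_vertices(bmr_W, conductance_W_per_C, tb_C, max_multiplier,
                     ta_min_C=-40.0):
    """Ordered vertices of the passive-thermoregulation region.

    Bounded below by M = BMR, above by M = max_multiplier * BMR, on the
    right by the dissipation line M = C * (Tb - Ta), and closed on the
    left at `ta_min_C` (the floor and ceiling are parallel, so a finite
    polygon needs a cold-side cutoff).  Counter-clockwise order starting
    at the lower-left vertex.
    """
    if max_multiplier <= 1:
        raise ValueError("max_multiplier must exceed 1")
    lower_right = passive_limit(bmr_W, conductance_W_per_C, tb_C, 1.0)
    upper_right = passive_limit(bmr_W, conductance_W_per_C, tb_C,
                                max_multiplier)
    if upper_right <= ta_min_C:
        raise ValueError(
            "inconsistent bounds: the metabolic ceiling never intersects "
            "the dissipation line above ta_min_C")
    return [
        (ta_min_C, bmr_W),
        (lower_right, bmr_W),
        (upper_right, max_multiplier * bmr_W),
        (ta_min_C, max_multiplier * bmr_W),
    ]


def polygon_area(vertices):
    """Shoelace area of an ordered vertex list (degC x Watts)."""
    area = 0.0
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


@dataclass
class ThermoPolygon:
    """Passive heat-balance geometry for one parameter set."""

    bmr_W: float
    conductance_W_per_C: float
    tb_C: float
    activity_multiplier: float = 4.0

    def __post_init__(self):
        if self.activity_multiplier < 1:
            raise ValueError("activity multiplier must be >= 1")
        self.ta_max_passive_C = passive_limit(
            self.bmr_W, self.conductance_W_per_C, self.tb_C,
            self.activity_multiplier)

    def vertices(self, ta_min_C=-40.0):
        return polygon_vertices(self.bmr_W, self.conductance_W_per_C,
                                self.tb_C, self.activity_multiplier,
                                ta_min_C=ta_min_C)

    def to_dict(self, ta_min_C=-40.0):
        return {
            "bmr_W": self.bmr_W,
            "conductance_W_per_C": self.conductance_W_per_C,
            "tb_C": self.tb_C,
            "activity_multiplier": self.activity_multiplier,
            "ta_max_passive_C": self.ta_max_passive_C,
            "vertices": self.vertices(ta_min_C),
        }

    def plot(self, ax=None, ta_min_C=-40.0):
        """Diagnostic figure of the polygon and the dissipation line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        verts = self.vertices(ta_min_C) + [self.vertices(ta_min_C)[0]]
        xs, ys = zip(*verts)
        ax.fill(xs, ys, alpha=0.25)
        ax.plot(xs, ys)
        ax.axvline(self.ta_max_passive_C, linestyle=":")
        ax.set_xlabel("environmental temperature (degC)")
        ax.set_ylabel("metabolic heat production (W)")
        ax.set_title(f"passive limit {self.ta_max_passive_C:.1f} degC at "
                     f"{self.activity_multiplier:g} x BMR")
        return ax
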