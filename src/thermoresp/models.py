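"""Mixed-model inference above the trait inflection points.

Random-intercept linear mixed models (bird identity as the grouping
factor) are fitted by maximum likelihood — not REML, so log-likelihoods
are comparable across fixed-effect structures — and compared by AICc over
the marginality-respecting candidate set

    {1}, {Ta}, {Mb}, {Ta + Mb}, {Ta + Mb + Ta:Mb}

("dredging" the global model Ta * Mb).  Akaike weights quantify relative
support; a top-model weight above 0.90 counts as overwhelming support.
Influence of individual birds is measured by a grouped Cook's distance
(leave-one-bird-out refits over the fixed effects); any bird with D > 1
triggers a Huber-weighted robust refit of the same model.

The module-level functions are the primitive operations; the
:class:`HeatResponseModel` / :class:`HeatResponseResults` pair bundles the
whole above-inflection workflow for one trait in a statsmodels-style
model/results interface.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM

from .segmented import SegmentedRegression

log = logging.getLogger(__name__)

#: Fixed-effect candidate set respecting marginality (interaction only
#: together with both main effects).
CANDIDATE_TERMS = [
    (),
    ("Ta",),
    ("Mb",),
    ("Ta", "Mb"),
    ("Ta", "Mb", "Ta:Mb"),
]

_TERM_COLUMNS = {"Ta": "Ta_C", "Mb": "mass_g"}

Z95 = 1.959963984540054


class FitFailure(RuntimeError):
    """A candidate mixed-model fit did not converge."""


def _design(df, terms):
    X = pd.DataFrame(index=df.index)
    X["Intercept"] = 1.0
    for term in terms:
        if term == "Ta:Mb":
            if not {"Ta", "Mb"} <= set(terms):
                raise ValueError("interaction requires both main effects")
            X["Ta:Mb"] = df["Ta_C"].to_numpy() * df["mass_g"].to_numpy()
        elif term in _TERM_COLUMNS:
            X[term] = df[_TERM_COLUMNS[term]].to_numpy()
        else:
            raise ValueError(f"unknown fixed-effect term {term!r}")
    return X


@dataclass
class CandidateModel:
    """One fitted random-intercept LMM with its selection statistics."""

    terms: tuple
    k: int
    n_obs: int
    n_groups: int
    loglik: float
    aicc: float
    estimates: dict            # per-term: beta, se, ci_low, ci_high, t
    re_variance: float
    residual_variance: float
    boundary: bool = False
    robust: bool = False
    delta_aicc: float = np.nan
    weight: float = np.nan
    result: object = field(default=None, repr=False, compare=False)

    def to_row(self):
        return {
            "terms": " + ".join(self.terms) if self.terms else "1",
            "k": self.k, "loglik": self.loglik, "aicc": self.aicc,
            "delta_aicc": self.delta_aicc, "weight": self.weight,
        }


def _wrap_fit(result, terms, n_obs, n_groups, boundary, robust=False):
    X_names = ["Intercept", *terms]
    beta = result.fe_params
    se = result.bse_fe
    estimates = {}
    for name in X_names:
        b, s = float(beta[name]), float(se[name])
        estimates[name] = {
            "beta": b, "se": s,
            "ci_low": b - Z95 * s, "ci_high": b + Z95 * s,
            "t": b / s if s > 0 else np.inf,
        }
    k = len(X_names) + 2  # fixed effects + RE variance + residual variance
    return CandidateModel(
        terms=tuple(terms), k=k, n_obs=n_obs, n_groups=n_groups,
        loglik=float(result.llf),
        aicc=aicc(float(result.llf), k, n_obs),
        estimates=estimates,
        re_variance=float(np.asarray(result.cov_re)[0, 0]),
        residual_variance=float(result.scale),
        boundary=boundary, robust=robust, result=result,
    )


def fit_lmm(df, trait, terms=("Ta",), group="bird_id"):
    """ML fit of a random-intercept LMM for `trait` with the given terms.

    Returns a :class:`CandidateModel`.  A random-intercept variance pinned
    at the zero boundary is retained but flagged (`boundary=True`).
    """
    if df[group].nunique() < 2:
        raise ValueError("need at least 2 birds for a random intercept")
    if len(df) < len(terms) + 4:
        raise ValueError("too few observations for this fixed-effect set")
    y = df[trait].to_numpy(float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite trait values")
    X = _design(df, terms)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = MixedLM(y, X, groups=df[group].to_numpy())
        result = None
        for method in (None, "powell", "cg"):
            try:
                result = (model.fit(reml=False) if method is None
                          else model.fit(reml=False, method=method))
            except (np.linalg.LinAlgError, ValueError):
                continue
            if np.isfinite(result.llf) and np.all(np.isfinite(result.fe_params)):
                break
            result = None
        if result is None:
            raise FitFailure(f"mixed-model fit failed for terms {terms}")
    boundary = float(np.asarray(result.cov_re)[0, 0]) < 1e-8 or any(
        "boundary" in str(w.message).lower() for w in caught)
    return _wrap_fit(result, terms, len(df), df[group].nunique(), boundary)


def aicc(loglik, k, n):
    """AICc = -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def akaike_weights(aicc_values):
    """Akaike weights w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2)."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size < 1:
        raise ValueError("need at least one model")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class ModelSelectionTable:
    """AICc-ranked candidate LMMs for one trait."""

    trait: str
    n_obs: int
    n_birds: int
    rows: list                      # CandidateModel, sorted by AICc
    retained: list                  # delta < delta_threshold
    overwhelming: bool
    failures: list = field(default_factory=list)

    def to_frame(self):
        return pd.DataFrame([m.to_row() for m in self.rows])

    def summary(self):
        head = (f"Model selection: {self.trait}  "
                f"(n={self.n_obs}, birds={self.n_birds}, ML + AICc)")
        frame = self.to_frame()
        body = frame.to_string(index=False,
                               float_format=lambda v: f"{v:.3f}")
        tail = ("top-model weight > 0.90: overwhelming support"
                if self.overwhelming else
                f"top-model weight {self.rows[0].weight:.3f}")
        return "\n".join([head, body, tail])


def dredge(df, trait, group="bird_id", delta_threshold=8.0,
           weight_threshold=0.90):
    """Fit and rank every marginality-respecting submodel of Ta * Mb.

    Weights are computed over all candidates that converged; models with
    delta AICc below `delta_threshold` form the retained set.
    """
    fits, failures = [], []
    for terms in CANDIDATE_TERMS:
        try:
            fits.append(fit_lmm(df, trait, terms, group=group))
        except (FitFailure, ValueError) as exc:
            failures.append({"terms": terms, "error": str(exc)})
            log.warning("candidate %s failed: %s", terms, exc)
    if not fits:
        raise FitFailure("every candidate model failed")
    w = akaike_weights([m.aicc for m in fits])
    amin = min(m.aicc for m in fits)
    for m, wi in zip(fits, w):
        m.delta_aicc = m.aicc - amin
        m.weight = float(wi)
    fits.sort(key=lambda m: m.aicc)
    retained = [m for m in fits if m.delta_aicc < delta_threshold]
    return ModelSelectionTable(
        trait=trait, n_obs=fits[0].n_obs, n_birds=fits[0].n_groups,
        rows=fits, retained=retained,
        overwhelming=bool(fits[0].weight > weight_threshold),
        failures=failures,
    )


def cooks_distance_by_bird(df, trait, terms=("Ta",), group="bird_id"):
    """Grouped Cook's distance: leave-one-bird-out refits over fixed effects.

    D_i = (b - b_(-i))' Cov(b)^{-1} (b - b_(-i)) / p, with Cov(b) the
    fixed-effect covariance of the full fit and p the number of fixed
    effects.  Birds whose deletion refit fails get NaN.
    """
    full = fit_lmm(df, trait, terms, group=group)
    names = ["Intercept", *terms]
    p = len(names)
    beta = np.array([full.estimates[n]["beta"] for n in names])
    cov = np.asarray(full.result.cov_params())[:p, :p]
    cov_inv = np.linalg.pinv(cov)
    out = {}
    for bird in pd.unique(df[group]):
        sub = df[df[group] != bird]
        try:
            part = fit_lmm(sub, trait, terms, group=group)
            diff = beta - np.array([part.estimates[n]["beta"] for n in names])
            out[bird] = float(diff @ cov_inv @ diff / p)
        except (FitFailure, ValueError) as exc:
            log.warning("leave-out refit failed for %s: %s", bird, exc)
            out[bird] = np.nan
    return pd.Series(out, name="cooks_distance")


def robust_fit(df, trait, terms=("Ta",), group="bird_id", huber_c=1.345,
               max_iter=25, tol=1e-6):
    """Huber-weighted robust refit of the random-intercept model.

    Iteratively winsorizes the marginal residuals at `huber_c` robust
    standard deviations (1.4826 x MAD, so the scale itself is immune to
    the outliers being guarded against) and refits the winsorized
    response by ML until the fixed effects stabilize.  With no outliers
    the estimates converge to (near) the plain ML fit; gross outliers are
    clipped and lose influence.  Deterministic for fixed data.
    """
    y0 = df[trait].to_numpy(float)
    X = _design(df, terms).to_numpy(float)
    work = df.copy()
    prev = None
    fitted = None
    for _ in range(max_iter):
        fitted = fit_lmm(work, trait, terms, group=group)
        names = ["Intercept", *terms]
        beta = np.array([fitted.estimates[n]["beta"] for n in names])
        resid = y0 - X @ beta
        s = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        s = max(s, 1e-12)
        z = resid / s
        work = work.assign(**{trait: X @ beta + np.clip(z, -huber_c, huber_c) * s})
        if prev is not None and np.max(np.abs(beta - prev)) < tol * (
                1.0 + np.max(np.abs(beta))):
            break
        prev = beta
    else:
        log.warning("robust fit did not fully stabilize in %d iterations",
                    max_iter)
    fitted.robust = True
    return fitted


@dataclass
class FoldChange:
    """Trait means at two extreme Ta bins and their ratio."""

    low_center_C: float
    high_center_C: float
    low_mean: float
    low_sd: float
    high_mean: float
    high_sd: float
    n_low: int
    n_high: int

    @property
    def ratio(self):
        return self.high_mean / self.low_mean

    @property
    def ratio_rounded(self):
        return round(self.ratio, 1)


def fold_ratio(low_mean, high_mean):
    """Fold change between two reported bin means, 1-decimal convention."""
    if low_mean <= 0:
        raise ValueError("low-bin mean must be positive")
    return round(high_mean / low_mean, 1)


def fold_changes(df, trait, low_center=26.0, high_center=43.0,
                 half_width=1.5, ta="Ta_C"):
    """Bin means +- SD at the Ta extremes and the high/low fold ratio."""
    lo = df[np.abs(df[ta] - low_center) <= half_width][trait]
    hi = df[np.abs(df[ta] - high_center) <= half_width][trait]
    if lo.empty or hi.empty:
        raise ValueError(
            f"empty Ta bin for {trait}: low n={len(lo)}, high n={len(hi)}")
    return FoldChange(
        low_center_C=low_center, high_center_C=high_center,
        low_mean=float(lo.mean()), low_sd=float(lo.std(ddof=1)) if len(lo) > 1 else 0.0,
        high_mean=float(hi.mean()), high_sd=float(hi.std(ddof=1)) if len(hi) > 1 else 0.0,
        n_low=int(len(lo)), n_high=int(len(hi)),
    )


class HeatResponseModel:
    """Above-inflection analysis of one trait: breakpoint, dredge, influence.

    Statsmodels-style wrapper: construct from a table of physiological
    points (one row per bird x Ta step), call :meth:`fit`, and inspect the
    returned :class:`HeatResponseResults`.

    Parameters
    ----------
    points : pandas.DataFrame
        Must carry `Ta_C`, `mass_g`, the trait column and the group column.
    trait : str
        Column holding the response (e.g. ``"Tb_C"``, ``"rmr_W"``).
    group : str
        Column holding bird identity.
    """

    def __init__(self, points, trait, group="bird_id"):
        for col in ("Ta_C", "mass_g", trait, group):
            if col not in points.columns:
                raise ValueError(f"points table lacks column {col!r}")
        self.points = points.reset_index(drop=True)
        self.trait = trait
        self.group = group

    @classmethod
    def from_points(cls, points, trait, group="bird_id"):
        return cls(points, trait, group=group)

    def fit(self, grid=0.01, boot=0, seed=None, delta_threshold=8.0,
            weight_threshold=0.90, cooks_threshold=1.0):
        """Run breakpoint location, model selection and influence checks.

        `boot >= 200` adds a cluster-bootstrap CI for the breakpoint.  Any
        bird with grouped Cook's distance above `cooks_threshold` triggers
        an automatic Huber robust refit of the top model.
        """
        seg_model = SegmentedRegression.from_dataframe(
            self.points, x="Ta_C", y=self.trait, groups=self.group)
        seg = seg_model.fit(grid=grid)
        if boot >= 200:
            seg.bootstrap_ci(B=boot, seed=seed)
        above = self.points[self.points["Ta_C"] > seg.psi]
        selection = dredge(above, self.trait, group=self.group,
                           delta_threshold=delta_threshold,
                           weight_threshold=weight_threshold)
        top = selection.rows[0]
        cooks = cooks_distance_by_bird(above, self.trait, top.terms,
                                       group=self.group)
        robust = None
        if np.nanmax(cooks.to_numpy()) > cooks_threshold:
            robust = robust_fit(above, self.trait, top.terms, group=self.group)
        return HeatResponseResults(
            model=self, breakpoint=seg, selection=selection, top=top,
            cooks=cooks, robust=robust, n_above=len(above))


@dataclass
class HeatResponseResults:
    """Joint results of the above-inflection workflow for one trait."""

    model: HeatResponseModel
    breakpoint: object
    selection: ModelSelectionTable
    top: CandidateModel
    cooks: pd.Series
    robust: object
    n_above: int

    @property
    def reported(self):
        """The model whose estimates should be reported (robust if used)."""
        return self.robust if self.robust is not None else self.top

    def summary(self):
        parts = [self.breakpoint.summary(), "", self.selection.summary(), ""]
        rep = self.reported
        label = "robust Huber refit" if rep.robust else "top model (ML)"
        parts.append(f"Estimates from {label}: "
                     f"{' + '.join(rep.terms) if rep.terms else '1'}")
        for name, est in rep.estimates.items():
            parts.append(
                f"  {name:<10} {est['beta']:>9.4f} +- {est['se']:.4f}  "
                f"95% CI [{est['ci_low']:.4f}, {est['ci_high']:.4f}]  "
                f"t = {est['t']:.2f}")
        parts.append(f"max grouped Cook's distance: "
                     f"{np.nanmax(self.cooks.to_numpy()):.3f}")
        return "\n".join(parts)

    def to_dict(self):
        rep = self.reported
        return {
            "breakpoint": self.breakpoint.to_dict(),
            "n_above": self.n_above,
            "selection": [m.to_row() for m in self.selection.rows],
            "overwhelming": self.selection.overwhelming,
            "top_terms": list(self.top.terms),
            "estimates": rep.estimates,
            "robust_used": rep.robust,
            "cooks_max": float(np.nanmax(self.cooks.to_numpy())),
        }
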