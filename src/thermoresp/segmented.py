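"""Two-segment (breakpoint) linear regression with bootstrap intervals.

Fits the continuous hinge model

    y = b0 + b1 * x + b2 * max(0, x - psi)

by profiling the residual sum of squares over a grid of candidate
breakpoints psi (default resolution 0.01 degC), refined by golden-section
search.  The fit is an ordinary pooled least-squares fit ("all birds
combined"); dependence within birds is restored for the confidence
interval by a case-resampling cluster bootstrap over birds.

The API mirrors statsmodels: build a :class:`SegmentedRegression` model
from data, call ``fit()``, get a :class:`SegmentedResults` object with the
estimates, diagnostics, a ``summary()`` table and a ``bootstrap_ci``
method.
"""

from __future__ import annotations

import numpy as np


class SegmentedRegression:
    """Continuous two-segment regression of `endog` on scalar `exog`.

    Parameters
    ----------
    endog : array-like
        Response values (one trait).
    exog : array-like
        Air temperatures.
    groups : array-like, optional
        Cluster labels (bird identity) used by the bootstrap CI.
    """

    def __init__(self, endog, exog, groups=None):
        y = np.asarray(endog, dtype=float)
        x = np.asarray(exog, dtype=float)
        if y.shape != x.shape or y.ndim != 1:
            raise ValueError("endog and exog must be 1-d arrays of equal length")
        if y.size < 6:
            raise ValueError("need at least 6 observations")
        if groups is not None:
            groups = np.asarray(groups)
            if groups.shape != y.shape:
                raise ValueError("groups must match endog length")
        self.endog = y
        self.exog = x
        self.groups = groups

    @classmethod
    def from_dataframe(cls, df, x="Ta_C", y=None, groups="bird_id"):
        g = df[groups].to_numpy() if groups in df.columns else None
        return cls(df[y].to_numpy(), df[x].to_numpy(), groups=g)

    # -- internal profiled-SSE machinery ---------------------------------

    def _prepare(self):
        order = np.argsort(self.exog, kind="stable")
        xs = self.exog[order]
        ys = self.endog[order]
        n = xs.size
        cum = {
            "x": np.concatenate([[0.0], np.cumsum(xs)]),
            "xx": np.concatenate([[0.0], np.cumsum(xs * xs)]),
            "y": np.concatenate([[0.0], np.cumsum(ys)]),
            "xy": np.concatenate([[0.0], np.cumsum(xs * ys)]),
        }
        syy = float(np.sum(ys * ys))
        return xs, ys, n, cum, syy

    @staticmethod
    def _sse_at(psi, xs, n, cum, syy):
        """SSE of the hinge fit at breakpoints `psi` (vectorized)."""
        psi = np.atleast_1d(np.asarray(psi, dtype=float))
        idx = np.searchsorted(xs, psi, side="right")
        k = n - idx
        sx_a = cum["x"][n] - cum["x"][idx]
        sxx_a = cum["xx"][n] - cum["xx"][idx]
        sy_a = cum["y"][n] - cum["y"][idx]
        sxy_a = cum["xy"][n] - cum["xy"][idx]
        sh = sx_a - k * psi
        shh = sxx_a - 2.0 * psi * sx_a + k * psi * psi
        sxh = sxx_a - psi * sx_a
        shy = sxy_a - psi * sy_a
        m = psi.size
        A = np.empty((m, 3, 3))
        A[:, 0, 0] = n
        A[:, 0, 1] = A[:, 1, 0] = cum["x"][n]
        A[:, 0, 2] = A[:, 2, 0] = sh
        A[:, 1, 1] = cum["xx"][n]
        A[:, 1, 2] = A[:, 2, 1] = sxh
        A[:, 2, 2] = shh
        b = np.stack([np.full(m, cum["y"][n]), np.full(m, cum["xy"][n]), shy],
                     axis=1)
        # ridge-free solve; singular candidates (no points above psi) get inf
        sse = np.full(m, np.inf)
        beta = np.zeros((m, 3))
        ok = k >= 1
        if ok.any():
            try:
                beta[ok] = np.linalg.solve(A[ok], b[ok][..., None])[..., 0]
            except np.linalg.LinAlgError:
                for i in np.flatnonzero(ok):
                    beta[i], *_ = np.linalg.lstsq(A[i], b[i], rcond=None)
            sse[ok] = syy - np.einsum("ij,ij->i", beta[ok], b[ok])
        return np.clip(sse, 0.0, None), beta

    def fit(self, grid=0.01, refine=True):
        """Profile the breakpoint over a grid and refine by golden section.

        Parameters
        ----------
        grid : float
            Candidate-breakpoint spacing in degC.  The candidate range is
            restricted so at least 3 distinct x values lie on each side.
        refine : bool
            Golden-section refinement within one grid cell of the best
            candidate (deterministic).
        """
        xs, ys, n, cum, syy = self._prepare()
        u = np.unique(xs)
        if u.size < 6:
            raise ValueError("x range degenerate: need >= 3 distinct values "
                             "on each side of any candidate breakpoint")
        lo, hi = u[2], u[-3]
        if hi <= lo:
            raise ValueError("x range degenerate for breakpoint search")
        candidates = np.arange(lo, hi + grid / 2.0, grid)
        sse, _ = self._sse_at(candidates, xs, n, cum, syy)
        best = int(np.argmin(sse))
        psi = float(candidates[best])

        if refine:
            a = max(lo, psi - grid)
            b = max(lo, min(hi, psi + grid))
            invphi = (np.sqrt(5.0) - 1.0) / 2.0
            c = b - invphi * (b - a)
            d = a + invphi * (b - a)
            fc = self._sse_at(c, xs, n, cum, syy)[0][0]
            fd = self._sse_at(d, xs, n, cum, syy)[0][0]
            for _ in range(60):
                if b - a < 1e-9:
                    break
                if fc < fd:
                    b, d, fd = d, c, fc
                    c = b - invphi * (b - a)
                    fc = self._sse_at(c, xs, n, cum, syy)[0][0]
                else:
                    a, c, fc = c, d, fd
                    d = a + invphi * (b - a)
                    fd = self._sse_at(d, xs, n, cum, syy)[0][0]
            psi_ref = 0.5 * (a + b)
            if self._sse_at(psi_ref, xs, n, cum, syy)[0][0] <= sse[best]:
                psi = float(psi_ref)

        sse_best, beta = self._sse_at(psi, xs, n, cum, syy)
        b0, b1, b2 = beta[0]

        # single straight line for comparison (nested null of the hinge)
        X1 = np.column_stack([np.ones(n), xs])
        coef_line, *_ = np.linalg.lstsq(X1, ys, rcond=None)
        sse_line = float(np.sum((ys - X1 @ coef_line) ** 2))

        return SegmentedResults(self, psi=psi, intercept=float(b0),
                                slope_below=float(b1),
                                slope_above=float(b1 + b2),
                                hinge_coef=float(b2), sse=float(sse_best[0]),
                                sse_line=sse_line, n_obs=int(n), grid=grid)


class SegmentedResults:
    """Results of a two-segment fit.

    Attributes
    ----------
    psi : float
        Estimated breakpoint (degC).
    slope_below, slope_above : float
        Segment slopes in trait units per degC.
    sse, sse_line : float
        Residual sum of squares of the hinge fit and of a single straight
        line (``sse <= sse_line`` always).
    ci95 : tuple or None
        Percentile bootstrap interval, populated by :meth:`bootstrap_ci`.
    """

    def __init__(self, model, psi, intercept, slope_below, slope_above,
                 hinge_coef, sse, sse_line, n_obs, grid):
        self.model = model
        self.psi = psi
        self.intercept = intercept
        self.slope_below = slope_below
        self.slope_above = slope_above
        self.hinge_coef = hinge_coef
        self.sse = sse
        self.sse_line = sse_line
        self.n_obs = n_obs
        self.grid = grid
        self.ci95 = None
        self.psi_boot = None

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return (self.intercept + self.slope_below * x
                + self.hinge_coef * np.clip(x - self.psi, 0.0, None))

    def bootstrap_ci(self, B=1000, seed=None, max_failure_frac=0.2):
        """95% percentile interval for psi by cluster (bird) bootstrap.

        Birds are resampled with replacement (case resampling); without
        group labels, rows are resampled.  Seeded and reproducible.
        """
        if B < 200:
            raise ValueError("use at least 200 bootstrap replicates")
        rng = np.random.default_rng(seed)
        y, x, g = self.model.endog, self.model.exog, self.model.groups
        psis, failures = [], 0
        if g is not None:
            labels = np.unique(g)
            index = {lab: np.flatnonzero(g == lab) for lab in labels}
        for _ in range(B):
            if g is not None:
                pick = rng.choice(labels, size=labels.size, replace=True)
                idx = np.concatenate([index[lab] for lab in pick])
            else:
                idx = rng.integers(0, y.size, size=y.size)
            try:
                res = SegmentedRegression(y[idx], x[idx]).fit(
                    grid=max(self.grid, 0.05), refine=True)
                psis.append(res.psi)
            except (ValueError, np.linalg.LinAlgError):
                failures += 1
        if failures > max_failure_frac * B:
            raise RuntimeError(
                f"breakpoint bootstrap unstable: {failures}/{B} replicate "
                "fits failed (x range too narrow or too few clusters)")
        psis = np.asarray(psis)
        self.psi_boot = psis
        self.ci95 = (float(np.percentile(psis, 2.5)),
                     float(np.percentile(psis, 97.5)))
        return self.ci95

    def summary(self):
        lines = [
            "Two-segment regression (continuous hinge)",
            "-" * 45,
            f"n_obs            {self.n_obs:>10d}",
            f"breakpoint psi   {self.psi:>10.3f} degC",
            f"slope below psi  {self.slope_below:>10.4f} per degC",
            f"slope above psi  {self.slope_above:>10.4f} per degC",
            f"intercept        {self.intercept:>10.4f}",
            f"SSE (hinge)      {self.sse:>10.5g}",
            f"SSE (one line)   {self.sse_line:>10.5g}",
        ]
        if self.ci95 is not None:
            lines.insert(4, f"psi 95% CI       [{self.ci95[0]:.2f}, "
                            f"{self.ci95[1]:.2f}] degC (cluster bootstrap)")
        return "\n".join(lines)

    def to_dict(self):
        return {
            "psi_C": self.psi, "ci95": self.ci95,
            "slope_below": self.slope_below, "slope_above": self.slope_above,
            "intercept": self.intercept, "sse": self.sse,
            "sse_line": self.sse_line, "n_obs": self.n_obs,
        }
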