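"""Dose-response normalisation and four-parameter logistic (4PL) fitting.

The response model is the standard Hill equation in log-concentration,

    y(x) = bottom + (top - bottom) / (1 + 10**((log10 EC50 - log10 x) * h)),

with EC50 the half-maximal concentration and h the Hill slope. Fitting is
nonlinear least squares over (bottom, top, log10 EC50, h) — or only
(log10 EC50, h) when the asymptotes are constrained to 0/100 — with a small
multi-start over the EC50 initialisation to dodge local minima. Confidence
intervals come from the asymptotic covariance of the estimator on the
log10 EC50 scale; the pointwise 95% band on the fitted curve uses the delta
method.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import optimize, stats

from .errors import DegenerateNormalizationError, FitError, ValidationError

__all__ = ["four_pl", "normalize", "fit_4pl", "DoseResponseFit"]


def four_pl(x, bottom, top, ec50, hill):
    """4PL response at concentration ``x`` (same units as ``ec50``)."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (
        1.0 + 10.0 ** ((np.log10(ec50) - np.log10(x)) * hill))


def normalize(concentrations, responses):
    """Affinely rescale responses so the smallest concentration-group mean
    maps to 0 and the largest to 100.

    Returns the rescaled responses in the original order; within-group
    ordering is preserved (the map is affine with positive slope).
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.shape != resp.shape:
        raise ValidationError("concentrations and responses differ in length")
    groups = np.unique(conc)
    if len(groups) < 2:
        raise ValidationError("need at least 2 concentration groups")
    means = np.array([resp[conc == g].mean() for g in groups])
    lo, hi = means.min(), means.max()
    if hi - lo == 0:
        raise DegenerateNormalizationError(
            "all concentration-group means are equal; normalisation undefined")
    return (resp - lo) / (hi - lo) * 100.0


@dataclass
class DoseResponseFit:
    """Result of a 4PL fit; ``ci95`` is on the EC50 (concentration) scale."""

    ec50: float
    log_ec50: float
    hill: float
    bottom: float
    top: float
    ci95: tuple[float, float]
    n_points: int
    constrained: bool
    rss: float
    cov: np.ndarray = dc_field(repr=False, default=None)
    _dof: int = dc_field(repr=False, default=0)

    def predict(self, x):
        return four_pl(x, self.bottom, self.top, self.ec50, self.hill)

    def confidence_band(self, x_grid, level: float = 0.95):
        """Delta-method pointwise confidence band for the mean curve.

        Returns ``(lower, upper)`` arrays over ``x_grid``.
        """
        x_grid = np.asarray(x_grid, dtype=float)
        theta = self._theta()
        grads = np.empty((len(x_grid), len(theta)))
        eps = 1e-6
        for k in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += eps
            tm[k] -= eps
            grads[:, k] = (self._curve(tp, x_grid) -
                           self._curve(tm, x_grid)) / (2 * eps)
        var = np.einsum("ij,jk,ik->i", grads, self.cov, grads)
        tcrit = stats.t.ppf(0.5 + level / 2, self._dof)
        y = self.predict(x_grid)
        half = tcrit * np.sqrt(np.maximum(var, 0.0))
        return y - half, y + half

    def _theta(self):
        if self.constrained:
            return np.array([self.log_ec50, self.hill])
        return np.array([self.bottom, self.top, self.log_ec50, self.hill])

    def _curve(self, theta, x):
        if self.constrained:
            return four_pl(x, 0.0, 100.0, 10.0 ** theta[0], theta[1])
        return four_pl(x, theta[0], theta[1], 10.0 ** theta[2], theta[3])


def fit_4pl(x, y, constrain: bool = False, n_starts: int = 3,
            max_restarts: int = 5) -> DoseResponseFit:
    """Least-squares 4PL fit of responses ``y`` (%) vs concentrations ``x``.

    With ``constrain=True`` the asymptotes are fixed at 0 and 100 (the
    convention after :func:`normalize`). Fitting happens in log10
    concentration space with ``n_starts`` EC50 initialisations around the
    median log-concentration; raises :class:`FitError` if no start converges.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0):
        raise ValidationError("concentrations must be strictly positive")
    if x.shape != y.shape:
        raise ValidationError("x and y differ in length")
    n_par = 2 if constrain else 4
    if len(np.unique(x)) < (2 if constrain else 4):
        raise ValidationError(
            f"need at least {2 if constrain else 4} distinct concentrations")
    logx = np.log10(x)

    def residuals(theta):
        if constrain:
            le, h = theta
            pred = four_pl(x, 0.0, 100.0, 10.0 ** le, h)
        else:
            b, t, le, h = theta
            pred = four_pl(x, b, t, 10.0 ** le, h)
        return pred - y

    med = float(np.median(logx))
    span = max(logx.max() - logx.min(), 1.0)
    starts = []
    for offset in np.linspace(-span / 3, span / 3, n_starts):
        if constrain:
            starts.append([med + offset, 1.0])
        else:
            starts.append([float(y.min()), float(y.max()), med + offset, 1.0])
    best = None
    for theta0 in starts[: n_starts + max_restarts]:
        try:
            res = optimize.least_squares(residuals, theta0, method="lm",
                                         max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError("4PL fit failed to converge from all starts "
                       f"(n={len(x)}, constrain={constrain})")
    theta = best.x
    rss = float(2 * best.cost)
    dof = max(len(x) - n_par, 1)
    s2 = rss / dof
    J = best.jac
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(J.T @ J)
    le_idx = 0 if constrain else 2
    se_le = float(np.sqrt(max(cov[le_idx, le_idx], 0.0)))
    tcrit = stats.t.ppf(0.975, dof)
    le = float(theta[le_idx])
    ci = (10.0 ** (le - tcrit * se_le), 10.0 ** (le + tcrit * se_le))
    if constrain:
        bottom, top = 0.0, 100.0
        hill = float(theta[1])
    else:
        bottom, top, hill = float(theta[0]), float(theta[1]), float(theta[3])
    return DoseResponseFit(ec50=10.0 ** le, log_ec50=le, hill=hill,
                           bottom=bottom, top=top, ci95=ci, n_points=len(x),
                           constrained=constrain, rss=rss, cov=cov, _dof=dof)
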