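"""Monte Carlo-adjusted profile (MCAP) confidence intervals.

A Monte Carlo profile log likelihood consists of noisy evaluations
``l_k`` at focal-parameter values ``phi_k``.  Near its maximum the
profile is locally quadratic (the local-asymptotic-normality regime),
so the evaluations are modelled by a quadratic metamodel

    l_k = a + b*phi_k + c*phi_k**2 + eps_k,

with i.i.d. Monte Carlo errors ``eps_k`` and an additive constant bias
that is absorbed into ``a`` and cancels in the interval construction.
The curvature ``-2c`` estimates the marginal Fisher information for the
focal parameter, giving the statistical standard error of its MLE; the
regression covariance of ``(b, c)``, propagated through the metamodel
maximizer ``-b/(2c)`` by the delta method, gives the Monte Carlo
standard error.  The two combine in quadrature, and the usual
chi-squared profile cut-off is inflated accordingly:

    delta = (chi2_{1,1-alpha} / 2) * (se_stat^2 + se_mc^2) / se_stat^2.

The confidence interval is the level set of the loess-smoothed profile
at ``delta`` below its maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats

from .errors import DegenerateFitError, InsufficientPointsError, NonConcaveFitError
from .loess import (
    DEFAULT_GRID_SIZE,
    DEFAULT_SPAN,
    SmoothedProfile,
    SmootherSpec,
    loess_weights,
    smooth_profile,
)

logger = logging.getLogger(__name__)

_MIN_POINTS = 4


@dataclass(frozen=True)
class ProfilePoints:
    """Paired Monte Carlo profile evaluations ``(phi_k, loglik_k)``.

    ``phi`` is sorted ascending on construction; duplicate ``phi`` values
    are kept, representing independent replicate evaluations at the same
    focal-parameter value.
    """

    phi: np.ndarray
    loglik: np.ndarray

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=float)
        ll = np.asarray(self.loglik, dtype=float)
        if phi.ndim != 1 or phi.shape != ll.shape:
            raise ValueError("phi and loglik must be 1-d arrays of equal length")
        if phi.size < _MIN_POINTS:
            raise InsufficientPointsError(
                f"need at least {_MIN_POINTS} profile points, got {phi.size}"
            )
        if not (np.all(np.isfinite(phi)) and np.all(np.isfinite(ll))):
            raise ValueError("profile points must be finite")
        order = np.argsort(phi, kind="stable")
        object.__setattr__(self, "phi", phi[order])
        object.__setattr__(self, "loglik", ll[order])

    def __len__(self) -> int:
        return self.phi.size


@dataclass(frozen=True)
class QuadraticFit:
    """Weighted-regression quadratic metamodel ``a + b*phi + c*phi^2``.

    ``cov`` is the 3x3 covariance of ``(a, b, c)`` under the
    homoskedastic precision-weight convention: ``sigma2 * (X'WX)^{-1}``
    with the residual variance estimated from weighted residuals on
    ``K_eff - 3`` degrees of freedom, ``K_eff`` the number of
    positive-weight points.  ``residual_sd`` estimates the Monte Carlo
    noise scale of a unit-weight profile evaluation.
    """

    a: float
    b: float
    c: float
    cov: np.ndarray
    residual_sd: float
    weights: np.ndarray

    @property
    def coef(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    @property
    def vertex(self) -> float:
        """Maximizer ``-b/(2c)`` of the fitted quadratic."""
        return -self.b / (2.0 * self.c)


@dataclass(frozen=True)
class MCAPResult:
    """Output of the MCAP algorithm.

    ``ci`` is the level set of the smoothed profile ``delta`` below its
    maximum; ``lower_open``/``upper_open`` flag endpoints pinned at the
    profile's domain boundary (the data do not bound the interval on
    that side).  ``diagnostics`` records non-convex level sets and other
    warnings.
    """

    phi_hat: float
    se_stat: float
    se_mc: float
    se_total: float
    delta: float
    ci: tuple[float, float]
    lower_open: bool
    upper_open: bool
    smoothed: SmoothedProfile
    fit: QuadraticFit
    alpha: float
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        """Plain JSON-compatible summary (no arrays)."""
        return {
            "schema": 1,
            "phi_hat": self.phi_hat,
            "se_stat": self.se_stat,
            "se_mc": self.se_mc,
            "se_total": self.se_total,
            "delta": self.delta,
            "ci_lower": self.ci[0],
            "ci_upper": self.ci[1],
            "lower_open": self.lower_open,
            "upper_open": self.upper_open,
            "alpha": self.alpha,
            "quadratic": {"a": self.fit.a, "b": self.fit.b, "c": self.fit.c},
            "diagnostics": {
                k: v for k, v in self.diagnostics.items() if not isinstance(v, np.ndarray)
            },
        }


def fit_quadratic_metamodel(points: ProfilePoints, weights) -> QuadraticFit:
    """Weighted least-squares quadratic fit to the profile points.

    Weights are treated as precision (inverse-variance) weights, so they
    matter only up to a common scale.  For numerical conditioning the
    regression is computed on ``phi`` centred at its weighted mean and
    the coefficients and covariance are mapped back to the raw scale;
    this is exact and does not affect any result.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != points.phi.shape:
        raise ValueError("weights must match the number of profile points")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    pos = w > 0
    k_eff = int(np.count_nonzero(pos))
    if np.unique(points.phi[pos]).size < 3:
        raise DegenerateFitError(
            "fewer than 3 distinct phi values carry positive weight"
        )
    if k_eff < 4:
        raise InsufficientPointsError(
            "need at least 4 positive-weight points for the metamodel "
            "(3 coefficients + 1 residual degree of freedom)"
        )

    phi = points.phi[pos]
    ll = points.loglik[pos]
    wp = w[pos]
    m = np.average(phi, weights=wp)
    d = phi - m
    X = np.column_stack([np.ones_like(d), d, d * d])
    XtW = X.T * wp
    A = XtW @ X
    try:
        beta_c = np.linalg.solve(A, XtW @ ll)
        A_inv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise DegenerateFitError("weighted design matrix is singular") from exc

    resid = ll - X @ beta_c
    sigma2 = float(wp @ resid**2) / (k_eff - 3)
    cov_c = sigma2 * A_inv

    # map centred coefficients/covariance back to the raw phi scale:
    # a = a' - b'm + c'm^2, b = b' - 2c'm, c = c'
    T = np.array([[1.0, -m, m * m], [0.0, 1.0, -2.0 * m], [0.0, 0.0, 1.0]])
    beta = T @ beta_c
    cov = T @ cov_c @ T.T
    cov = 0.5 * (cov + cov.T)

    a, b, c = beta
    if c >= 0:
        raise NonConcaveFitError(
            f"quadratic metamodel is not concave (c = {c:.4g}); the profile "
            "shows no interior maximum at this scale — widen the profile "
            "range or add evaluation points"
        )
    return QuadraticFit(
        a=float(a),
        b=float(b),
        c=float(c),
        cov=cov,
        residual_sd=float(np.sqrt(sigma2)),
        weights=w,
    )


def se_stat_from_curvature(fit: QuadraticFit) -> float:
    """Statistical standard error from the metamodel curvature.

    The curvature ``-2c`` estimates the marginal Fisher information
    ``I`` of the focal parameter, so ``se_stat = (-2c)**-0.5``.
    """
    if fit.c >= 0:
        raise NonConcaveFitError("curvature requires c < 0")
    return float(1.0 / np.sqrt(-2.0 * fit.c))


def se_mc_delta_method(fit: QuadraticFit) -> float:
    """Monte Carlo standard error of the metamodel maximizer ``-b/(2c)``.

    Delta method through the regression covariance of ``(b, c)`` with
    gradient ``(-1/(2c), b/(2c^2))``.
    """
    if fit.c >= 0:
        raise NonConcaveFitError("delta method requires c < 0")
    b, c = fit.b, fit.c
    g = np.array([-1.0 / (2.0 * c), b / (2.0 * c * c)])
    sigma = fit.cov[1:, 1:]
    var = float(g @ sigma @ g)
    return float(np.sqrt(max(var, 0.0)))


def combine_se(se_stat: float, se_mc: float) -> float:
    """Combined standard error: statistical and Monte Carlo in quadrature."""
    if se_stat < 0 or se_mc < 0:
        raise ValueError("standard errors must be non-negative")
    return float(np.hypot(se_stat, se_mc))


def compute_cutoff(se_stat: float, se_mc: float, alpha: float = 0.05) -> float:
    """Monte Carlo-adjusted profile cut-off.

    ``delta = (chi2_{1,1-alpha}/2) * (se_stat^2 + se_mc^2) / se_stat^2``.
    With ``se_mc = 0`` this is the usual chi-squared profile cut-off
    (1.92 at the 95% level).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if se_stat <= 0:
        raise NonConcaveFitError("se_stat must be positive (valid curvature)")
    if se_mc < 0:
        raise ValueError("se_mc must be non-negative")
    chi = stats.chi2.ppf(1.0 - alpha, df=1)
    return float(chi / 2.0 * (se_stat**2 + se_mc**2) / se_stat**2)


def extract_ci(
    smoothed: SmoothedProfile, delta: float
) -> tuple[tuple[float, float], bool, bool, bool]:
    """Level set ``{phi : smoothed(phi) >= max - delta}`` of the profile.

    Returns ``((lower, upper), lower_open, upper_open, non_convex)``.
    The interval spans from the first up-crossing to the last
    down-crossing of the threshold, located by linear interpolation
    between adjacent grid points.  An endpoint where the profile never
    drops below the threshold is the domain boundary, flagged open.
    ``non_convex`` flags interior dips below the threshold (a multimodal
    smoothed profile).
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    grid = smoothed.grid
    fitted = smoothed.fitted
    thr = smoothed.max_value - delta
    above = fitted >= thr
    if not np.any(above):
        # only the refined maximum exceeds the threshold
        return (smoothed.argmax, smoothed.argmax), False, False, False

    idx = np.flatnonzero(above)
    first, last = idx[0], idx[-1]

    if first == 0:
        lower, lower_open = float(grid[0]), True
    else:
        lower = _cross(grid[first - 1], grid[first], fitted[first - 1], fitted[first], thr)
        lower_open = False
    if last == len(grid) - 1:
        upper, upper_open = float(grid[-1]), True
    else:
        upper = _cross(grid[last], grid[last + 1], fitted[last], fitted[last + 1], thr)
        upper_open = False

    non_convex = bool(np.any(~above[first : last + 1]))
    if non_convex:
        logger.warning(
            "smoothed profile dips below the cut-off inside the interval; "
            "the level set is not an interval (reporting its hull)"
        )
    return (lower, upper), lower_open, upper_open, non_convex


def _cross(x0: float, x1: float, y0: float, y1: float, thr: float) -> float:
    if y1 == y0:
        return float(x1)
    return float(x0 + (thr - y0) * (x1 - x0) / (y1 - y0))


def mcap(
    points: ProfilePoints | tuple,
    span: float = DEFAULT_SPAN,
    alpha: float = 0.05,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> MCAPResult:
    """Run the MCAP algorithm on a Monte Carlo profile.

    Steps: smooth the profile with a local quadratic smoother; take the
    smoothed argmax ``phi_hat``; fit the quadratic metamodel with the
    smoother's weights at ``phi_hat``; derive ``se_stat`` from the
    curvature and ``se_mc`` by the delta method; inflate the chi-squared
    cut-off; extract the confidence interval from the smoothed profile.
    """
    if not isinstance(points, ProfilePoints):
        points = ProfilePoints(*points)
    spec = SmootherSpec(span=span)

    smoothed = smooth_profile(points.phi, points.loglik, spec, grid_size)
    phi_hat = smoothed.argmax
    logger.info("smoothed profile maximum at phi = %.6g", phi_hat)

    w = loess_weights(phi_hat, points.phi, span)
    logger.debug("metamodel weights at phi_hat: %s", w)
    fit = fit_quadratic_metamodel(points, w)
    logger.debug(
        "metamodel (a, b, c) = (%.6g, %.6g, %.6g), residual sd %.4g",
        fit.a, fit.b, fit.c, fit.residual_sd,
    )

    se_stat = se_stat_from_curvature(fit)
    se_mc = se_mc_delta_method(fit)
    se_total = combine_se(se_stat, se_mc)
    delta = compute_cutoff(se_stat, se_mc, alpha)
    logger.info(
        "se_stat = %.4g, se_mc = %.4g, se_total = %.4g, cut-off delta = %.4g",
        se_stat, se_mc, se_total, delta,
    )

    ci, lower_open, upper_open, non_convex = extract_ci(smoothed, delta)
    diagnostics: dict[str, Any] = {
        "non_convex_level_set": non_convex,
        "metamodel_vertex": fit.vertex,
        "residual_sd": fit.residual_sd,
        "n_points": len(points),
        "span": span,
        "grid_size": grid_size,
    }
    return MCAPResult(
        phi_hat=phi_hat,
        se_stat=se_stat,
        se_mc=se_mc,
        se_total=se_total,
        delta=delta,
        ci=ci,
        lower_open=lower_open,
        upper_open=upper_open,
        smoothed=smoothed,
        fit=fit,
        alpha=alpha,
        diagnostics=diagnostics,
    )
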