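"""Local quadratic regression smoothing with tricube weights.

This is the classical single-predictor loess smoother restricted to
degree 2 and a tricube kernel: at each evaluation point a weighted
least-squares quadratic is fitted through the profile points, with
positive weight on the ``q = ceil(span * K)`` nearest design points.
No robustness (iterative re-weighting) passes are performed.

The smoother is evaluated exactly at every requested point (no
interpolation shortcut), so results are deterministic and reproducible
to floating precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateDesignError, DegenerateFitError, InsufficientPointsError

logger = logging.getLogger(__name__)

DEFAULT_SPAN = 0.75
DEFAULT_GRID_SIZE = 500

#: minimum positive-weight points needed for a local quadratic with a
#: residual degree of freedom
_MIN_POINTS = 4


@dataclass(frozen=True)
class SmootherSpec:
    """Configuration of the local quadratic smoother.

    Parameters
    ----------
    span : float
        Fraction ``lambda`` of the data receiving positive weight in each
        local regression, in ``(0, 1]``.  The neighbourhood size is
        ``q = ceil(span * K)`` and must be at least 4.
    """

    span: float = DEFAULT_SPAN
    degree: int = field(default=2, init=False)
    kernel: str = field(default="tricube", init=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.span <= 1.0:
            raise ValueError(f"span must be in (0, 1], got {self.span}")

    def neighborhood_size(self, n_points: int) -> int:
        q = int(np.ceil(self.span * n_points))
        if q < _MIN_POINTS:
            raise InsufficientPointsError(
                f"span {self.span} with K={n_points} gives a neighborhood of "
                f"{q} < {_MIN_POINTS} points; increase the span or add points"
            )
        return q


@dataclass(frozen=True)
class SmoothedProfile:
    """A smoothed profile log likelihood with its evaluation grid.

    Attributes
    ----------
    phi, loglik : ndarray
        The source Monte Carlo profile points.
    spec : SmootherSpec
        Smoother configuration used.
    grid : ndarray
        Ordered evaluation points covering ``[min(phi), max(phi)]``.
    fitted : ndarray
        Smoothed values on ``grid``.
    argmax : float
        Location of the smoothed maximum (grid search refined by a
        parabola through the bracketing triple).
    max_value : float
        Smoothed profile value at ``argmax``.
    """

    phi: np.ndarray
    loglik: np.ndarray
    spec: SmootherSpec
    grid: np.ndarray
    fitted: np.ndarray
    argmax: float
    max_value: float

    def __call__(self, x):
        """Evaluate the smoother at arbitrary points inside the domain."""
        return loess_eval(self.phi, self.loglik, x, self.spec)


def _validate_design(phi: np.ndarray) -> None:
    if phi.size < _MIN_POINTS:
        raise InsufficientPointsError(
            f"need at least {_MIN_POINTS} profile points, got {phi.size}"
        )
    if np.ptp(phi) == 0.0:
        raise DegenerateDesignError("all design points are identical")


def loess_weights(eval_point: float, design_points, span: float) -> np.ndarray:
    """Tricube weights at ``eval_point`` over the ``q`` nearest design points.

    ``w_k = (1 - (d_k / d_max)^3)^3`` for the ``q = ceil(span * K)``
    nearest points (ties at the neighbourhood boundary all included),
    zero elsewhere, where ``d_k = |phi_k - eval_point|`` and ``d_max``
    is the distance to the q-th nearest point.  If the q nearest points
    all coincide with ``eval_point`` (``d_max = 0``) the weights fall
    back to equal weight on the neighbourhood.
    """
    phi = np.asarray(design_points, dtype=float)
    _validate_design(phi)
    q = SmootherSpec(span=span).neighborhood_size(phi.size)

    d = np.abs(phi - float(eval_point))
    d_max = np.partition(d, q - 1)[q - 1]
    w = np.zeros_like(d)
    if d_max == 0.0:
        # eval point sits on >= q duplicated design points
        w[d == 0.0] = 1.0
        return w / w.sum()
    inside = d <= d_max
    u = d[inside] / d_max
    w[inside] = (1.0 - u**3) ** 3
    return w


def _quadratic_wls(phi, ll, w, x0: float) -> np.ndarray:
    """Weighted LS quadratic through (phi, ll), centred at x0.

    Returns coefficients (beta0, beta1, beta2) of
    ``beta0 + beta1*(phi-x0) + beta2*(phi-x0)**2``.
    """
    pos = w > 0
    if np.unique(phi[pos]).size < 3:
        raise DegenerateFitError(
            "fewer than 3 distinct design points carry positive weight"
        )
    d = phi[pos] - x0
    X = np.column_stack([np.ones_like(d), d, d * d])
    sw = np.sqrt(w[pos])
    beta, *_ = np.linalg.lstsq(X * sw[:, None], ll[pos] * sw, rcond=None)
    return beta


def _weights_batch(xs: np.ndarray, phi: np.ndarray, span: float) -> np.ndarray:
    """Tricube weight matrix, one row per evaluation point."""
    q = SmootherSpec(span=span).neighborhood_size(phi.size)
    d = np.abs(phi[None, :] - xs[:, None])  # (G, K)
    d_max = np.partition(d, q - 1, axis=1)[:, q - 1]
    w = np.zeros_like(d)
    ok = d_max > 0.0
    if np.any(ok):
        u = np.clip(d[ok] / d_max[ok, None], 0.0, 1.0)
        w[ok] = (1.0 - u**3) ** 3
    if np.any(~ok):
        dup = d[~ok] == 0.0
        w[~ok] = dup / dup.sum(axis=1, keepdims=True)
    return w


def loess_eval(phi, loglik, eval_points, spec: SmootherSpec):
    """Evaluate the local quadratic smoother at one or more points.

    At each evaluation point the weighted quadratic is centred there, so
    its intercept is the fitted value.  Array evaluation solves the
    per-point 3x3 weighted normal equations in a single batched pass.
    """
    phi = np.asarray(phi, dtype=float)
    ll = np.asarray(loglik, dtype=float)
    _validate_design(phi)
    scalar = np.ndim(eval_points) == 0
    xs = np.atleast_1d(np.asarray(eval_points, dtype=float))

    w = _weights_batch(xs, phi, spec.span)  # (G, K)
    if scalar and np.unique(phi[w[0] > 0]).size < 3:
        raise DegenerateFitError(
            "fewer than 3 distinct design points carry positive weight"
        )
    d = phi[None, :] - xs[:, None]
    X = np.stack([np.ones_like(d), d, d * d], axis=-1)  # (G, K, 3)
    Xw = X * w[:, :, None]
    A = np.einsum("gki,gkj->gij", Xw, X)
    rhs = np.einsum("gki,k->gi", Xw, ll)
    try:
        beta = np.linalg.solve(A, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError as exc:
        raise DegenerateFitError("weighted design matrix is singular") from exc
    out = beta[:, 0]
    if not np.all(np.isfinite(out)):
        raise DegenerateFitError("smoother produced non-finite fitted values")
    return float(out[0]) if scalar else out


def _refine_argmax(grid, fitted):
    """Parabolic refinement of the grid argmax through its bracketing triple."""
    i = int(np.argmax(fitted))
    if i == 0 or i == len(grid) - 1:
        return float(grid[i])
    x = grid[i - 1 : i + 2]
    y = fitted[i - 1 : i + 2]
    # vertex of the interpolating parabola
    coef = np.polyfit(x - x[1], y, 2)
    if coef[0] >= 0:  # flat or convex triple: keep the grid point
        return float(grid[i])
    return float(x[1] - coef[1] / (2.0 * coef[0]))


def smooth_profile(
    phi,
    loglik,
    spec: SmootherSpec | None = None,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> SmoothedProfile:
    """Smooth a Monte Carlo profile on a uniform grid and locate its maximum.

    Parameters
    ----------
    phi, loglik : array-like
        Profile points (focal parameter values, Monte Carlo log-likelihood
        evaluations).  ``phi`` need not be distinct: replicated Monte Carlo
        evaluations at the same point are legitimate.
    spec : SmootherSpec, optional
        Smoother configuration; defaults to span 0.75.
    grid_size : int
        Number of uniform evaluation points over ``[min(phi), max(phi)]``;
        must be at least ``len(phi)``.
    """
    spec = spec or SmootherSpec()
    phi = np.asarray(phi, dtype=float)
    ll = np.asarray(loglik, dtype=float)
    _validate_design(phi)
    if grid_size < phi.size:
        raise ValueError(f"grid_size {grid_size} < number of points {phi.size}")
    if spec.span * phi.size < 10:
        logger.warning(
            "span * K = %.1f < 10: the local quadratic rests on very few "
            "points; consider a larger span",
            spec.span * phi.size,
        )

    grid = np.linspace(phi.min(), phi.max(), grid_size)
    fitted = loess_eval(phi, ll, grid, spec)
    if not np.all(np.isfinite(fitted)):
        raise DegenerateFitError("smoother produced non-finite fitted values")

    x_hat = _refine_argmax(grid, fitted)
    max_value = float(loess_eval(phi, ll, x_hat, spec))
    # the refined vertex can only be accepted if it genuinely improves
    if max_value < fitted.max():
        x_hat = float(grid[int(np.argmax(fitted))])
        max_value = float(fitted.max())
    return SmoothedProfile(
        phi=phi,
        loglik=ll,
        spec=spec,
        grid=grid,
        fitted=fitted,
        argmax=x_hat,
        max_value=max_value,
    )
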