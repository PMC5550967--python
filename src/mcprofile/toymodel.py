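"""Lognormal latent-variable toy model with a Monte Carlo likelihood.

Data are i.i.d. lognormal: ``Y_n | X_n ~ lognormal(X_n, sigma^2)`` with
latent ``X_n ~ N(phi, sigma^2)``, so marginally
``log Y_n ~ N(phi, 2 sigma^2)``.  The marginal density is available in
closed form, but the model is deliberately accessed through a Monte
Carlo estimator that integrates the latent variable with ``J`` draws
per observation:

    fhat(y_n; phi, sigma) = (1/J) sum_j f_LN(y_n; phi + sigma*eps_nj, sigma^2)

with a fixed standard-normal array ``eps`` (one block of ``J`` draws
per observation) tied to a seed.  At a fixed seed the Monte Carlo log
likelihood is a smooth deterministic function of ``(phi, sigma)``, so a
profile over ``phi`` can be computed by ordinary numerical maximization
over ``sigma``; across seeds the evaluations are noisy, reproducing the
regime in which Monte Carlo profile methods operate.  The closed-form
marginal model provides the exact profile as an oracle.

The Monte Carlo density is unbiased for the marginal density on the
natural scale, so by Jensen's inequality the Monte Carlo log likelihood
is biased downwards — the bias is constant to first order near the
maximum and cancels in the interval construction.

Seeding uses the counter-based Philox generator: distinct seeds give
streams that behave like independent random sequences, and the data
stream is kept separate from the Monte Carlo stream so statistical and
Monte Carlo error can be toggled independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))

#: sigma search interval (log scale) for the fixed-seed profile maximization
SIGMA_BOUNDS = (0.05, 20.0)
_SIGMA_XATOL = 1e-6

DEFAULT_N = 50
DEFAULT_J = 3
DEFAULT_PHI0 = 0.0
DEFAULT_SIGMA2 = 1.0
DEFAULT_GRID_K = 30
#: profile grid half-width in units of the exact standard error of phi_hat
GRID_HALFWIDTH_SE = 5.0


@dataclass(frozen=True)
class ToyConfig:
    """Configuration of one toy-model experiment.

    Parameters
    ----------
    n : int
        Number of lognormal observations.
    j : int
        Monte Carlo draws per observation in the density estimator.
    phi0 : float
        True log-mean parameter.
    sigma2 : float
        True variance component (``log Y`` has variance ``2*sigma2``).
    grid_k : int
        Number of profile evaluation points.
    alpha : float
        Significance level for intervals.
    """

    n: int = DEFAULT_N
    j: int = DEFAULT_J
    phi0: float = DEFAULT_PHI0
    sigma2: float = DEFAULT_SIGMA2
    grid_k: int = DEFAULT_GRID_K
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 observations")
        if self.j < 1:
            raise ValueError("need at least 1 Monte Carlo draw per observation")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.grid_k < 4:
            raise ValueError("profile grid needs at least 4 points")


def simulate_data(config: ToyConfig, data_rng: np.random.Generator) -> np.ndarray:
    """Simulate ``y_1:N`` from the latent-variable lognormal model.

    ``y_n = exp(x_n + sigma0 * z_n)`` with ``x_n ~ N(phi0, sigma0^2)``
    and ``z_n ~ N(0, 1)``, so marginally ``log y_n ~ N(phi0, 2 sigma0^2)``.
    """
    sigma0 = np.sqrt(config.sigma2)
    x = data_rng.normal(config.phi0, sigma0, size=config.n)
    z = data_rng.standard_normal(config.n)
    return np.exp(x + sigma0 * z)


def draw_eps(config: ToyConfig, seed: int) -> np.ndarray:
    """The fixed ``(N, J)`` standard-normal array for Monte Carlo seed ``seed``.

    One block of ``J`` draws per observation, generated once per seed by a
    counter-based Philox stream and reused for every ``(phi, sigma)``.
    """
    rng = np.random.Generator(np.random.Philox(key=seed))
    return rng.standard_normal((config.n, config.j))


def _log_f_ln(log_y: np.ndarray, mu, tau2) -> np.ndarray:
    """Log lognormal density ``f_LN(y; mu, tau^2)`` given ``log y``."""
    return -log_y - 0.5 * (np.log(tau2) + _LOG_2PI + (log_y - mu) ** 2 / tau2)


def exact_loglik(y: np.ndarray, phi: float, sigma: float) -> float:
    """Exact marginal log likelihood: ``log Y_n ~ N(phi, 2 sigma^2)``."""
    log_y = np.log(np.asarray(y, dtype=float))
    return float(np.sum(_log_f_ln(log_y, phi, 2.0 * sigma**2)))


def mc_density(y: float, phi: float, sigma: float, eps: np.ndarray) -> float:
    """Monte Carlo estimate of the marginal density of one observation.

    ``(1/J) sum_j f_LN(y; phi + sigma*eps_j, sigma^2)``; unbiased for the
    exact marginal ``f_LN(y; phi, 2 sigma^2)`` on the natural scale.
    """
    if y <= 0:
        raise ValueError("lognormal observations must be positive")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    eps = np.asarray(eps, dtype=float)
    log_y = np.log(float(y))
    log_terms = _log_f_ln(log_y, phi + sigma * eps, sigma**2)
    return float(np.exp(logsumexp(log_terms) - np.log(eps.size)))


def mc_loglik(y: np.ndarray, phi: float, sigma: float, eps: np.ndarray) -> float:
    """Fixed-seed Monte Carlo log likelihood over the whole sample.

    ``eps`` has shape ``(N, J)``: observation ``n`` uses its own block
    ``eps[n]``.  Deterministic given ``(y, phi, sigma, eps)``.  A zero
    density estimate for any observation yields ``-inf`` with a warning.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("lognormal observations must be positive")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    eps = np.asarray(eps, dtype=float)
    if eps.shape[0] != y.size:
        raise ValueError("eps must have one row per observation")
    log_y = np.log(y)[:, None]
    log_terms = _log_f_ln(log_y, phi + sigma * eps, sigma**2)  # (N, J)
    per_obs = logsumexp(log_terms, axis=1) - np.log(eps.shape[1])
    if np.any(np.isneginf(per_obs)):
        logger.warning("zero Monte Carlo density estimate; log likelihood is -inf")
    return float(np.sum(per_obs))


def profile_point(
    y: np.ndarray, phi: float, eps: np.ndarray
) -> tuple[float, float, bool]:
    """Maximize the fixed-seed Monte Carlo log likelihood over ``sigma``.

    Bounded scalar optimization on ``log sigma`` over
    ``[log 0.05, log 20]`` to absolute tolerance 1e-6.  Returns
    ``(profile value, sigma_hat, ok)``; ``ok`` is False when the
    optimizer did not converge (callers should exclude the point with a
    warning).
    """
    y = np.asarray(y, dtype=float)
    log_y = np.log(y)
    eps = np.asarray(eps, dtype=float)
    lo, hi = np.log(SIGMA_BOUNDS)

    inv_j = np.log(eps.shape[1])

    def neg_ll(log_sigma: float) -> float:
        sigma = np.exp(log_sigma)
        log_terms = _log_f_ln(log_y[:, None], phi + sigma * eps, sigma**2)
        return -float(np.sum(logsumexp(log_terms, axis=1) - inv_j))

    res = minimize_scalar(
        neg_ll, bounds=(lo, hi), method="bounded", options={"xatol": _SIGMA_XATOL}
    )
    ok = bool(res.success) and np.isfinite(res.fun)
    if not ok:
        logger.warning("sigma optimization failed at phi = %.4g: %s", phi, res.message)
    return float(-res.fun), float(np.exp(res.x)), ok


def exact_profile(y: np.ndarray, phi) -> np.ndarray | float:
    """Closed-form exact profile log likelihood of the marginal model.

    With ``v(phi) = mean((log y_n - phi)^2)``, the MLE of ``2 sigma^2``
    at fixed ``phi``, the profile is
    ``-(N/2) log(2 pi v(phi)) - N/2 - sum(log y_n)``.
    """
    log_y = np.log(np.asarray(y, dtype=float))
    phi_arr = np.atleast_1d(np.asarray(phi, dtype=float))
    v = np.mean((log_y[None, :] - phi_arr[:, None]) ** 2, axis=1)
    if np.any(v == 0):
        raise ValueError("degenerate sample: all log y equal phi")
    n = log_y.size
    out = -0.5 * n * (np.log(2.0 * np.pi * v) + 1.0) - np.sum(log_y)
    return float(out[0]) if np.ndim(phi) == 0 else out


def exact_profile_ci(y: np.ndarray, delta: float) -> tuple[float, float]:
    """Closed-form level set of the exact profile at ``delta`` below its max.

    The exact profile peaks at ``phi_hat = mean(log y)`` with
    ``v(phi) = v_hat + (phi - phi_hat)^2``, so the drop is
    ``(N/2) log(1 + (phi - phi_hat)^2 / v_hat)`` and the interval is
    ``phi_hat +/- sqrt(v_hat * (exp(2 delta / N) - 1))``.
    """
    log_y = np.log(np.asarray(y, dtype=float))
    n = log_y.size
    phi_hat = float(np.mean(log_y))
    v_hat = float(np.var(log_y))
    half = np.sqrt(v_hat * np.expm1(2.0 * delta / n))
    return (phi_hat - half, phi_hat + half)


def profile_grid(y: np.ndarray, config: ToyConfig) -> np.ndarray:
    """Default profile evaluation grid.

    ``grid_k`` equally spaced points centred on the exact MLE
    ``mean(log y)`` with half-width ``5 * sqrt(2 sigma_hat^2 / N)``
    (five exact standard errors, covering the inferentially relevant
    region).
    """
    log_y = np.log(np.asarray(y, dtype=float))
    phi_hat = float(np.mean(log_y))
    se = float(np.sqrt(np.var(log_y) / log_y.size))
    half = GRID_HALFWIDTH_SE * se
    return np.linspace(phi_hat - half, phi_hat + half, config.grid_k)


def profile_eps(config: ToyConfig, mc_seed: int, k: int) -> np.ndarray:
    """Independent ``(N, J)`` epsilon blocks for ``k`` profile points.

    Each profile point gets its own seed (derived deterministically from
    ``mc_seed``), so the Monte Carlo evaluations are independent across
    points — seed fixing makes each single maximization deterministic,
    not the profile as a whole.  Returns shape ``(k, N, J)``.
    """
    seeds = np.random.SeedSequence(mc_seed).generate_state(k)
    return np.stack([draw_eps(config, int(s)) for s in seeds])


def mc_profile(
    y: np.ndarray, grid: np.ndarray, eps: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixed-seed Monte Carlo profile over ``grid``.

    ``eps`` of shape ``(K, N, J)`` assigns each grid point its own
    epsilon block (independent evaluations, the standard construction);
    shape ``(N, J)`` shares one block across the whole profile
    (perfectly correlated evaluations, useful for diagnostics only).
    Returns ``(loglik, sigma_hat, ok)`` arrays, one entry per grid
    point; failed maximizations are flagged, not dropped here.
    """
    grid = np.asarray(grid, dtype=float)
    eps = np.asarray(eps, dtype=float)
    ll = np.empty(grid.size)
    sig = np.empty(grid.size)
    ok = np.empty(grid.size, dtype=bool)
    for i, phi in enumerate(grid):
        block = eps if eps.ndim == 2 else eps[i]
        ll[i], sig[i], ok[i] = profile_point(y, phi, block)
    return ll, sig, ok


@dataclass(frozen=True)
class ToyReplicate:
    """One simulated dataset with its profiles and intervals."""

    y: np.ndarray
    grid: np.ndarray
    mc_loglik: np.ndarray
    sigma_hat: np.ndarray
    exact_loglik: np.ndarray
    mcap_ci: tuple[float, float] | None
    exact_ci: tuple[float, float]
    mcap_covers: bool | None
    exact_covers: bool
    flagged: bool
    flag_reason: str = ""
    mcap_result: object = field(default=None, repr=False)
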