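"""Polya-gamma draws and the conjugate Gaussian update for logistic models.

A PG(b, psi) auxiliary variable renders a binomial or multinomial logistic
likelihood conditionally Gaussian in its linear coefficients, so every
coefficient block can be updated with a (possibly truncated) normal draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import ndtr, ndtri

from ._pg_kernels import pg_draw_array, _pg_mean_var

__all__ = [
    "draw_pg",
    "draw_pg_series",
    "pg_mean",
    "pg_var",
    "GaussianUpdate",
    "logistic_gaussian_update",
    "sample_truncated_normal",
]


def pg_mean(b, psi):
    """Closed-form mean b * tanh(psi/2) / (2 psi), continuous at psi = 0."""
    b = np.asarray(b, dtype=float)
    psi = np.abs(np.asarray(psi, dtype=float))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(psi < 1e-8, b / 4.0, b * np.tanh(psi / 2.0) / (2.0 * psi))
    return out[()] if out.ndim == 0 else out


def pg_var(b, psi):
    """Closed-form variance; limit b/24 as psi -> 0."""
    b = np.atleast_1d(np.asarray(b, dtype=float))
    psi = np.atleast_1d(np.abs(np.asarray(psi, dtype=float)))
    b, psi = np.broadcast_arrays(b, psi)
    out = np.array([_pg_mean_var(bi, pi)[1] for bi, pi in zip(b.ravel(), psi.ravel())])
    return out.reshape(b.shape).squeeze()[()]


def draw_pg(b, psi, rng, size: int | None = None):
    """Draw from PG(b, psi).

    ``b`` must be a positive integer (or an array of them); a draw with
    integer shape is distributed as the sum of b independent PG(1, psi)
    variables.  With scalar arguments and ``size`` given, returns that many
    i.i.d. draws; otherwise the output matches the broadcast input shape.
    """
    b_arr = np.asarray(b)
    psi_arr = np.asarray(psi, dtype=float)
    if size is not None:
        if b_arr.ndim or psi_arr.ndim:
            raise ValueError("size only applies to scalar b, psi")
        b_arr = np.full(size, b_arr)
        psi_arr = np.full(size, psi_arr)
    b_arr, psi_arr = np.broadcast_arrays(b_arr, psi_arr)
    scalar = b_arr.ndim == 0
    out = pg_draw_array(np.atleast_1d(b_arr), np.atleast_1d(psi_arr), rng)
    return float(out[0]) if scalar and size is None else out


def draw_pg_series(b: int, psi: float, rng, n_terms: int = 200) -> float:
    """Reference draw via the truncated infinite sum of gammas.

    PG(b, psi) = (1 / 2 pi^2) * sum_k g_k / ((k - 1/2)^2 + psi^2 / (4 pi^2)),
    g_k ~ Gamma(b, 1).  Slow; for validating the rejection sampler only.
    The expected mass of the dropped tail is added back as a constant so the
    truncation does not bias the mean.
    """
    if b <= 0:
        raise ValueError("b must be positive")
    k = np.arange(1, n_terms + 1)
    denom = (k - 0.5) ** 2 + psi ** 2 / (4.0 * np.pi ** 2)
    g = rng.gamma(shape=b, scale=1.0, size=n_terms)
    tail = float(pg_mean(b, psi)) - b * np.sum(1.0 / denom) / (2.0 * np.pi ** 2)
    return float(np.sum(g / denom) / (2.0 * np.pi ** 2) + max(tail, 0.0))


@dataclass
class GaussianUpdate:
    """Posterior mean/covariance of one conditionally Gaussian block."""

    mean: np.ndarray
    cov: np.ndarray
    chol_precision: np.ndarray  # lower Cholesky factor of the precision

    def sample(self, rng) -> np.ndarray:
        """Draw from N(mean, cov) via the precision Cholesky factor."""
        z = rng.standard_normal(self.mean.shape[0])
        return self.mean + solve_triangular(self.chol_precision.T, z, lower=False)


def logistic_gaussian_update(
    design: np.ndarray,
    kappa: np.ndarray,
    omega: np.ndarray,
    prior_sd: float,
    offset: np.ndarray | float = 0.0,
) -> GaussianUpdate:
    """Conjugate Gaussian update for PG-augmented logistic coefficients.

    Precision = design' diag(omega) design + I / prior_sd^2 and
    mean = Sigma design' (kappa + omega * offset); ``offset`` is the
    subtracted competing-category term in the multinomial case and zero for
    plain binomial logistic regression.  Solved against the precision
    Cholesky factor, never by explicit inversion.
    """
    design = np.asarray(design, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    if (omega <= 0).any():
        raise ValueError("PG weights must be positive")
    p = design.shape[1]
    precision = (design * omega[:, None]).T @ design + np.eye(p) / prior_sd ** 2
    rhs = design.T @ (kappa + omega * np.asarray(offset, dtype=float))
    c, low = cho_factor(precision, lower=True)
    mean = cho_solve((c, low), rhs)
    cov = cho_solve((c, low), np.eye(p))
    return GaussianUpdate(mean=mean, cov=cov, chol_precision=np.tril(c))


_TAIL_SWITCH = 5.0


def sample_truncated_normal(mean, sd, lower, rng, size: int | None = None):
    """Draw from Normal(mean, sd^2) conditioned on value > lower.

    Uses inverse-CDF sampling in survival space for moderate truncation and
    Robert's translated-exponential rejection deep in the upper tail, so
    extreme bounds stay numerically stable.  ``lower = -inf`` gives an
    untruncated draw.
    """
    if np.any(np.asarray(sd) <= 0):
        raise ValueError("sd must be positive")
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    lower = np.asarray(lower, dtype=float)
    scalar = mean.ndim == 0 and sd.ndim == 0 and lower.ndim == 0 and size is None
    if size is not None:
        mean, sd, lower = (np.broadcast_to(x, size).copy() for x in (mean, sd, lower))
    mean, sd, lower = np.atleast_1d(*np.broadcast_arrays(mean, sd, lower))
    a = (lower - mean) / sd  # standardized bound
    out = np.empty(a.shape)
    easy = a < _TAIL_SWITCH
    if easy.any():
        sf = ndtr(-a[easy])  # P(Z > a)
        u = rng.random(int(easy.sum()))
        out[easy] = -ndtri(sf * u)
    hard = ~easy
    for i in np.flatnonzero(hard):
        out[i] = _robert_tail(a[i], rng)
    result = mean + sd * out
    # guard against boundary round-off at moderate truncation
    clip = np.isfinite(lower) & (result <= lower)
    result[clip] = np.nextafter(lower[clip], np.inf)
    return float(result[0]) if scalar else result


def _robert_tail(a: float, rng) -> float:
    alpha = 0.5 * (a + np.sqrt(a * a + 4.0))
    while True:
        x = a + rng.standard_exponential() / alpha
        if rng.random() <= np.exp(-0.5 * (x - alpha) ** 2):
            return x
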