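"""Low-level Polya-gamma rejection sampler (Devroye-type for shape 1).

Implemented after the standard alternating-series algorithm of Polson,
Scott & Windle (BayesLogit): the target PG(1, z) variable equals J*(1, z/2)/4
where J* is sampled by a mixture of a truncated exponential and a truncated
inverse-Gaussian proposal plus an alternating-series accept/reject step.
Integer shapes b > 1 are drawn as sums of b unit draws up to a cutoff, beyond
which a moment-matched normal approximation is used (the PG(b, z) variable is
a sum of b i.i.d. terms, so the CLT error there is negligible).

All kernels are compiled with numba when available; the pure-Python bodies
are the fallback and are exercised directly in the test suite.
"""

from __future__ import annotations

import math

import numpy as np

_TRUNC = 0.64
_NORMAL_APPROX_CUTOFF = 170


def _norm_cdf(x: float) -> float:
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


def _a_coef(n: int, x: float) -> float:
    # alternating-series coefficients of the J*(1, 0) density
    h = n + 0.5
    if x > _TRUNC:
        return math.pi * h * math.exp(-h * h * math.pi * math.pi * x / 2.0)
    return (2.0 / math.pi / x) ** 1.5 * math.pi * h * math.exp(-2.0 * h * h / x)


def _mass_texpon(z: float) -> float:
    # P(choose the right/exponential piece of the proposal)
    t = _TRUNC
    fz = 0.125 * math.pi * math.pi + 0.5 * z * z
    b = math.sqrt(1.0 / t) * (t * z - 1.0)
    a = -math.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = math.log(fz) + fz * t
    xb = x0 - z + math.log(_norm_cdf(b))
    xa = x0 + z + math.log(_norm_cdf(a))
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


def _rtigauss(z: float, rng) -> float:
    # inverse-Gaussian(mu = 1/z, lambda = 1) truncated to (0, TRUNC)
    t = _TRUNC
    x = t + 1.0
    if z < 1.0 / t:  # mu > t: scaled-chi rejection
        while True:
            while True:
                e1 = rng.standard_exponential()
                e2 = rng.standard_exponential()
                if e1 * e1 <= 2.0 * e2 / t:
                    break
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            if rng.random() <= math.exp(-0.5 * z * z * x):
                return x
    mu = 1.0 / z
    while x > t:
        y = rng.standard_normal()
        y = y * y
        mu_y = mu * y
        x = mu + 0.5 * mu * mu_y - 0.5 * mu * math.sqrt(4.0 * mu_y + mu_y * mu_y)
        if rng.random() > mu / (mu + x):
            x = mu * mu / x
    return x


def _pg1(psi: float, rng) -> float:
    # one PG(1, psi) draw
    z = abs(psi) * 0.5
    fz = 0.125 * math.pi * math.pi + 0.5 * z * z
    p_right = _mass_texpon(z)
    while True:
        if rng.random() < p_right:
            x = _TRUNC + rng.standard_exponential() / fz
        else:
            x = _rtigauss(z, rng)
        s = _a_coef(0, x)
        y = rng.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    return 0.25 * x
            else:
                s += _a_coef(n, x)
                if y > s:
                    break


def _pg_mean_var(b: float, psi: float) -> tuple[float, float]:
    z = abs(psi)
    if z < 1e-8:
        return b / 4.0, b / 24.0
    mean = b * math.tanh(z / 2.0) / (2.0 * z)
    sech2 = 1.0 / math.cosh(z / 2.0) ** 2
    var = b * (math.sinh(z) - z) * sech2 / (4.0 * z ** 3)
    return mean, var


def _pg_draw_into(b: np.ndarray, psi: np.ndarray, out: np.ndarray, rng) -> None:
    """Fill ``out[i]`` with a PG(b[i], psi[i]) draw for every i."""
    for i in range(b.shape[0]):
        bi = b[i]
        if bi <= _NORMAL_APPROX_CUTOFF:
            acc = 0.0
            for _ in range(bi):
                acc += _pg1(psi[i], rng)
            out[i] = acc
        else:
            mean, var = _pg_mean_var(float(bi), psi[i])
            draw = mean + math.sqrt(var) * rng.standard_normal()
            while draw <= 0.0:  # PG support is positive; tail clip is astronomically rare
                draw = mean + math.sqrt(var) * rng.standard_normal()
            out[i] = draw


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _norm_cdf = njit(cache=True)(_norm_cdf)
    _a_coef = njit(cache=True)(_a_coef)
    _mass_texpon = njit(cache=True)(_mass_texpon)
    _rtigauss = njit(cache=True)(_rtigauss)
    _pg1 = njit(cache=True)(_pg1)
    _pg_mean_var = njit(cache=True)(_pg_mean_var)
    _pg_draw_into = njit(cache=True)(_pg_draw_into)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False


def pg_draw_array(b, psi, rng) -> np.ndarray:
    """Vector of PG(b_i, psi_i) draws; b integer-valued and positive."""
    b = np.asarray(b)
    psi = np.asarray(psi, dtype=np.float64)
    if b.shape != psi.shape:
        raise ValueError("b and psi must have the same shape")
    if not np.issubdtype(b.dtype, np.integer):
        if not np.all(b == np.floor(b)):
            raise ValueError("only integer PG shapes are supported")
        b = b.astype(np.int64)
    else:
        b = b.astype(np.int64)
    if (b <= 0).any():
        raise ValueError("PG shape b must be positive (skip zero-count cells)")
    out = np.empty(b.shape[0], dtype=np.float64)
    _pg_draw_into(b, psi, out, rng)
    return out
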