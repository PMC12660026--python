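"""Three-step hierarchical Gibbs sampler.

Each outer iteration updates, in order: the latent profile classes (exact
categorical conditionals over all 2**K classes), the item coefficients
(PG-augmented truncated-normal coordinate updates, with at most 2**K
auxiliaries per item because respondents are aggregated by profile class),
and the transition-regression coefficients (PG-augmented multinomial-logit
updates run for ``m`` inner sweeps per outer iteration).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

from ._pg_kernels import pg_draw_array
from .model_core import (
    Dimensions,
    ItemDesign,
    ItemParams,
    ProfileCodec,
    ProfileState,
    QMatrix,
    ResponseData,
    TrajectoryCodec,
    TransitionDesign,
    TransitionParams,
    build_item_design,
    transition_linear_predictors,
)
from .pg_augmentation import logistic_gaussian_update, sample_truncated_normal

logger = logging.getLogger("tdcm")

__all__ = [
    "SamplerConfig",
    "TDCMModel",
    "PosteriorDraws",
    "sample_alpha_step",
    "sample_lambda_step",
    "sample_gamma_step",
    "run_gibbs",
]


@dataclass
class SamplerConfig:
    """Chain-length, inner-loop, and prior settings for the Gibbs sampler."""

    M: int = 5000
    burn: int = 1000
    m: int = 1
    sigma_lambda: float = 2.0
    sigma_gamma: float = 2.0
    seed: int = 0
    time_constrained_lambda: bool = True
    store_alpha: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.burn < self.M:
            raise ValueError("need 0 <= burn < M")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.sigma_lambda <= 0 or self.sigma_gamma <= 0:
            raise ValueError("prior standard deviations must be positive")


@dataclass
class TDCMModel:
    """Static model structure: dimensions, codecs, and design matrices."""

    dims: Dimensions
    Q: QMatrix
    item_designs: list[ItemDesign]
    transition_design: TransitionDesign
    pcodec: ProfileCodec
    tcodec: TrajectoryCodec

    @classmethod
    def build(
        cls,
        Q: QMatrix,
        T: int,
        n_respondents: int,
        X: pd.DataFrame | None = None,
        covariate_map=None,
        include_interactions: bool = False,
    ) -> "TDCMModel":
        dims = Dimensions(I=n_respondents, J=Q.J, K=Q.K, T=T)
        tdesign = TransitionDesign(
            X, K=Q.K, T=T, covariate_map=covariate_map, n_respondents=n_respondents
        )
        if tdesign.I != n_respondents:
            raise ValueError(
                f"covariate table has {tdesign.I} rows but data has {n_respondents} respondents"
            )
        return cls(
            dims=dims,
            Q=Q,
            item_designs=build_item_design(Q, include_interactions=include_interactions),
            transition_design=tdesign,
            pcodec=ProfileCodec(Q.K),
            tcodec=TrajectoryCodec(T),
        )


# ---------------------------------------------------------------------------
# Step 1: latent profile classes
# ---------------------------------------------------------------------------


def _item_prob_table(model: TDCMModel, lam: ItemParams, t: int) -> np.ndarray:
    """(C, J) response probabilities per profile class for time t."""
    C = model.dims.C
    out = np.empty((C, model.dims.J))
    for j, dj in enumerate(model.item_designs):
        out[:, j] = expit(dj.delta @ lam.item_vector(j, t))
    return out


def _transition_log_probs(model: TDCMModel, gamma: TransitionParams) -> np.ndarray:
    """(I, K, R) log type-probabilities per respondent and attribute."""
    I, K, R = model.dims.I, model.dims.K, model.dims.R
    ltp = np.empty((I, K, R))
    for k in range(K):
        eta = transition_linear_predictors(model.transition_design, gamma, k)
        ltp[:, k, :] = eta - logsumexp(eta, axis=1, keepdims=True)
    return ltp


def alpha_log_conditionals(
    model: TDCMModel,
    data: ResponseData,
    lam: ItemParams,
    alpha: np.ndarray,
    t: int,
    ltp: np.ndarray | None = None,
    gamma: TransitionParams | None = None,
) -> np.ndarray:
    """Unnormalized (I, C) log conditional of every class at time t.

    Combines the item likelihood of the time-t response block with the
    trajectory-type probabilities implied by holding the classes at all other
    time points at their current values.
    """
    if ltp is None:
        if gamma is None:
            raise ValueError("need either precomputed log type-probs or gamma")
        ltp = _transition_log_probs(model, gamma)
    probs = _item_prob_table(model, lam, t)  # (C, J)
    logp = np.log(probs)
    log1mp = np.log1p(-probs)
    Yt = data.block(t).astype(float)
    loglik = Yt @ (logp - log1mp).T + log1mp.sum(axis=1)  # (I, C)

    bits = model.pcodec.all_profiles[alpha]  # (I, T, K)
    w = model.tcodec.weights  # (T,)
    code_other = np.tensordot(bits, w, axes=([1], [0])) - w[t] * bits[:, t, :]  # (I, K)
    cand_bits = model.pcodec.all_profiles  # (C, K)
    ridx = code_other[:, :, None] + w[t] * cand_bits.T[None, :, :]  # (I, K, C)
    trans = np.take_along_axis(ltp, ridx, axis=2).sum(axis=1)  # (I, C)

    logw = loglik + trans
    if not np.isfinite(logw).all():
        raise FloatingPointError("non-finite profile conditional weight")
    return logw


def alpha_conditional_probs(model, data, lam, alpha, t, gamma) -> np.ndarray:
    """Normalized version of :func:`alpha_log_conditionals` (for checking)."""
    logw = alpha_log_conditionals(model, data, lam, alpha, t, gamma=gamma)
    logw = logw - logsumexp(logw, axis=1, keepdims=True)
    return np.exp(logw)


def sample_alpha_step(
    model: TDCMModel,
    data: ResponseData,
    lam: ItemParams,
    gamma: TransitionParams,
    alpha: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One full scan of exact categorical profile updates, t ascending.

    Respondents are conditionally independent given the parameters, so each
    time point is updated as one vectorized block; time points are scanned
    sequentially because each conditional depends on the classes at the
    other times.
    """
    alpha = alpha.copy()
    ltp = _transition_log_probs(model, gamma)
    for t in range(model.dims.T):
        logw = alpha_log_conditionals(model, data, lam, alpha, t, ltp=ltp)
        gumbel = rng.gumbel(size=logw.shape)
        alpha[:, t] = np.argmax(logw + gumbel, axis=1)
    return alpha


# ---------------------------------------------------------------------------
# Step 2: item coefficients
# ---------------------------------------------------------------------------


def _update_item_vector(
    design: ItemDesign,
    lam_j: np.ndarray,
    n_c: np.ndarray,
    s_c: np.ndarray,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """PG-augmented coordinate-wise truncated-normal update of one item."""
    nonempty = np.flatnonzero(n_c > 0)
    if nonempty.size == 0:  # prior-only draw, mains reflected positive
        draw = rng.normal(0.0, sigma, size=lam_j.shape)
        main = np.isfinite(design.lower_bounds) & (design.lower_bounds == 0.0)
        draw[main] = np.abs(draw[main])
        return draw
    delta = design.delta[nonempty].astype(float)  # (C*, P)
    psi = delta @ lam_j
    omega = pg_draw_array(n_c[nonempty], psi, rng)
    kappa = s_c[nonempty] - n_c[nonempty] / 2.0
    lam_new = lam_j.copy()
    eta = delta @ lam_new
    for p in range(design.n_params):
        d_p = delta[:, p]
        eta_minus = eta - d_p * lam_new[p]
        prec = float(np.sum(omega * d_p * d_p) + 1.0 / sigma ** 2)
        mean = float(np.sum(d_p * (kappa - omega * eta_minus))) / prec
        sd = prec ** -0.5
        lam_new[p] = sample_truncated_normal(mean, sd, design.lower_bounds[p], rng)
        eta = eta_minus + d_p * lam_new[p]
    return lam_new


def sample_lambda_step(
    model: TDCMModel,
    data: ResponseData,
    alpha: np.ndarray,
    config: SamplerConfig,
    lam: ItemParams,
    rng: np.random.Generator,
) -> ItemParams:
    """Update every item's coefficient vector given the current profiles.

    Respondent-time cells are aggregated per profile class (counts and
    correct counts), so one PG auxiliary is drawn per item and nonempty
    class.  In time-constrained mode the aggregation pools all time points;
    otherwise each time point carries its own coefficient vector.
    """
    C = model.dims.C
    sigma = config.sigma_lambda
    if config.time_constrained_lambda:
        alpha_flat = alpha.T.ravel()  # time-major, matches column layout
        n_c = np.bincount(alpha_flat, minlength=C).astype(np.int64)
        new_values = []
        for j, dj in enumerate(model.item_designs):
            y_flat = data.Y[:, j::model.dims.J].T.ravel().astype(float)
            s_c = np.bincount(alpha_flat, weights=y_flat, minlength=C)
            new_values.append(_update_item_vector(dj, lam.item_vector(j), n_c, s_c, sigma, rng))
        return ItemParams(values=new_values, time_varying=False)
    new_values = []
    n_ct = [np.bincount(alpha[:, t], minlength=C).astype(np.int64) for t in range(model.dims.T)]
    for j, dj in enumerate(model.item_designs):
        rows = np.empty((model.dims.T, dj.n_params))
        for t in range(model.dims.T):
            y = data.Y[:, t * model.dims.J + j].astype(float)
            s_c = np.bincount(alpha[:, t], weights=y, minlength=C)
            rows[t] = _update_item_vector(dj, lam.item_vector(j, t), n_ct[t], s_c, sigma, rng)
        new_values.append(rows)
    return ItemParams(values=new_values, time_varying=True)


# ---------------------------------------------------------------------------
# Step 3: transition coefficients
# ---------------------------------------------------------------------------


def sample_gamma_step(
    model: TDCMModel,
    alpha: np.ndarray,
    gamma: TransitionParams,
    config: SamplerConfig,
    rng: np.random.Generator,
) -> TransitionParams:
    """Update the multinomial-logit coefficients for every attribute.

    For each attribute the inner loop runs ``m`` sweeps; within a sweep the
    non-baseline types are visited in order and each block gets a PG draw
    against the log-sum-exp of the competing categories (computed from the
    freshest coefficient values) followed by a conjugate Gaussian draw.
    """
    tdesign = model.transition_design
    state = ProfileState(alpha, K=model.dims.K)
    z = state.trajectory_types(model.pcodec, model.tcodec)  # (I, K), 1-based
    gamma = gamma.copy()
    R = model.dims.R
    ones_b = np.ones(model.dims.I, dtype=np.int64)
    for k in range(model.dims.K):
        eta = transition_linear_predictors(tdesign, gamma, k)  # (I, R)
        z_k = z[:, k]
        for _ in range(config.m):
            for r in range(2, R + 1):
                others = np.delete(np.arange(R), r - 1)
                C_off = logsumexp(eta[:, others], axis=1)  # competing-category term
                psi = eta[:, r - 1] - C_off
                omega = pg_draw_array(ones_b, psi, rng)
                kappa = (z_k == r).astype(float) - 0.5
                upd = logistic_gaussian_update(
                    tdesign.design(k, r), kappa, omega, config.sigma_gamma, offset=C_off
                )
                gamma.gamma[(k, r)] = upd.sample(rng)
                eta[:, r - 1] = tdesign.design(k, r) @ gamma.gamma[(k, r)]
    return gamma


# ---------------------------------------------------------------------------
# Chain driver and storage
# ---------------------------------------------------------------------------


@dataclass
class PosteriorDraws:
    """Stored post-burn-in draws of lambda, gamma, and alpha."""

    model: TDCMModel
    config: SamplerConfig
    lambda_draws: list  # per item: (n_draws, P_j) or (n_draws, T, P_j)
    gamma_draws: dict  # (k, r) -> (n_draws, p)
    alpha_draws: np.ndarray | None  # (n_draws, I, T) or None
    time_varying: bool = False

    @property
    def n_draws(self) -> int:
        return self.lambda_draws[0].shape[0]

    def parameter_table(self) -> pd.DataFrame:
        """Long-format table: one row per (iteration, parameter)."""
        rows = []
        attr = self.model.Q.attribute_names
        for j, draws in enumerate(self.lambda_draws):
            labels = self.model.item_designs[j].column_labels(attr)
            if self.time_varying:
                for t in range(draws.shape[1]):
                    for p, lab in enumerate(labels):
                        rows.append((f"lambda[item{j + 1},t{t + 1},{lab}]", draws[:, t, p]))
            else:
                for p, lab in enumerate(labels):
                    rows.append((f"lambda[item{j + 1},{lab}]", draws[:, p]))
        for (k, r), draws in sorted(self.gamma_draws.items()):
            labels = self.model.transition_design.labels(k, r)
            for p, lab in enumerate(labels):
                rows.append((f"gamma[{attr[k]},type{r},{lab}]", draws[:, p]))
        n = self.n_draws
        out = pd.DataFrame(
            {
                "iteration": np.tile(np.arange(n), len(rows)),
                "parameter": np.repeat([name for name, _ in rows], n),
                "value": np.concatenate([vals for _, vals in rows]),
            }
        )
        return out

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd, and central 95% interval per parameter."""
        table = self.parameter_table()
        g = table.groupby("parameter", sort=False)["value"]
        out = g.agg(["mean", "std"])
        out["q2.5"] = g.quantile(0.025)
        out["q97.5"] = g.quantile(0.975)
        return out

    def to_csv(self, path) -> None:
        self.parameter_table().to_csv(path, index=False)

    def to_json_summary(self, path) -> None:
        summ = self.summary()
        payload = {
            name: {
                "mean": row["mean"],
                "sd": row["std"],
                "q2.5": row["q2.5"],
                "q97.5": row["q97.5"],
            }
            for name, row in summ.iterrows()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _validate(model: TDCMModel, data: ResponseData) -> None:
    if data.I != model.dims.I:
        raise ValueError(f"data has {data.I} respondents, model expects {model.dims.I}")
    if data.J != model.dims.J:
        raise ValueError(f"data has {data.J} items per time, model expects {model.dims.J}")
    if data.T != model.dims.T:
        raise ValueError(f"data has {data.T} time points, model expects {model.dims.T}")


def _init_state(model: TDCMModel, config: SamplerConfig, rng: np.random.Generator):
    dims = model.dims
    alpha = rng.integers(0, dims.C, size=(dims.I, dims.T))
    lam_values = []
    for dj in model.item_designs:
        if config.time_constrained_lambda:
            v = rng.normal(0.0, config.sigma_lambda, size=dj.n_params)
            main = dj.lower_bounds == 0.0
            v[main] = np.abs(v[main])
            lam_values.append(v)
        else:
            v = rng.normal(0.0, config.sigma_lambda, size=(dims.T, dj.n_params))
            main = dj.lower_bounds == 0.0
            v[:, main] = np.abs(v[:, main])
            lam_values.append(v)
    lam = ItemParams(values=lam_values, time_varying=not config.time_constrained_lambda)
    gamma = TransitionParams(
        {
            (k, r): rng.normal(0.0, config.sigma_gamma, size=model.transition_design.n_params(k, r))
            for k in range(dims.K)
            for r in range(2, dims.R + 1)
        }
    )
    return alpha, lam, gamma


def run_gibbs(
    data: ResponseData,
    model: TDCMModel,
    config: SamplerConfig,
    init: tuple | None = None,
) -> PosteriorDraws:
    """Run the full three-step chain for M iterations and keep post-burn draws.

    Identical seeds yield bit-identical draws.  ``init`` optionally overrides
    the random initialization with an ``(alpha, lam, gamma)`` triple.
    """
    _validate(model, data)
    rng = np.random.default_rng(config.seed)
    if init is None:
        alpha, lam, gamma = _init_state(model, config, rng)
    else:
        alpha, lam, gamma = init
        alpha = np.array(alpha, dtype=np.int64)

    n_keep = config.M - config.burn
    if config.time_constrained_lambda:
        lambda_store = [np.empty((n_keep, dj.n_params)) for dj in model.item_designs]
    else:
        lambda_store = [np.empty((n_keep, model.dims.T, dj.n_params)) for dj in model.item_designs]
    gamma_store = {
        (k, r): np.empty((n_keep, model.transition_design.n_params(k, r)))
        for k in range(model.dims.K)
        for r in range(2, model.dims.R + 1)
    }
    alpha_store = (
        np.empty((n_keep, model.dims.I, model.dims.T), dtype=np.int16)
        if config.store_alpha
        else None
    )

    monitor_keys = sorted(gamma_store)[: 3]
    running = {key: 0.0 for key in monitor_keys}
    for it in range(config.M):
        alpha = sample_alpha_step(model, data, lam, gamma, alpha, rng)
        lam = sample_lambda_step(model, data, alpha, config, lam, rng)
        gamma = sample_gamma_step(model, alpha, gamma, config, rng)
        if it >= config.burn:
            idx = it - config.burn
            for j in range(model.dims.J):
                lambda_store[j][idx] = lam.values[j]
            for key in gamma_store:
                gamma_store[key][idx] = gamma.gamma[key]
            if alpha_store is not None:
                alpha_store[idx] = alpha
        if (it + 1) % 100 == 0:
            for key in monitor_keys:
                running[key] = float(gamma.gamma[key][0])
            msg = ", ".join(f"gamma[{k},{r}][0]={v:+.3f}" for (k, r), v in running.items())
            logger.info("iteration %d/%d: %s", it + 1, config.M, msg)

    return PosteriorDraws(
        model=model,
        config=config,
        lambda_draws=lambda_store,
        gamma_draws=gamma_store,
        alpha_draws=alpha_store,
        time_varying=not config.time_constrained_lambda,
    )
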