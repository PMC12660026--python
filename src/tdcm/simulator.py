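"""Synthetic data generation and parameter-recovery studies.

Four canonical designs are provided, mirroring the recovery-study layouts the
method is evaluated on: (1) a two-time-point design with a balanced binary
treatment on the gain transition, (2) the same plus multi-attribute items
with interaction terms, (3) extra continuous covariates on the gain
transition, and (4) a three-time-point design with the treatment applied to
every type whose first transition involves a change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gibbs_engine import PosteriorDraws, SamplerConfig, TDCMModel, run_gibbs
from .model_core import (
    ItemParams,
    ProfileCodec,
    QMatrix,
    ResponseData,
    TrajectoryCodec,
    TransitionParams,
    item_response_prob,
    transition_type_probs,
)

__all__ = ["SimulationDesign", "make_design", "simulate_dataset", "replicate_study"]


@dataclass
class SimulationDesign:
    """Everything needed to draw one synthetic dataset."""

    I: int
    T: int
    Q: QMatrix
    true_lambda: ItemParams
    true_gamma: TransitionParams
    covariate_map: dict
    covariate_sampler: object  # callable (I, rng) -> DataFrame
    include_interactions: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        from .model_core import build_item_design

        designs = build_item_design(self.Q, include_interactions=self.include_interactions)
        for j, dj in enumerate(designs):
            lam = self.true_lambda.item_vector(j)
            mains = dj.lower_bounds == 0.0
            if np.any(np.asarray(lam)[mains] <= 0):
                raise ValueError(f"true main effects of item {j} must be positive")
        R = 2 ** self.T
        for key in self.covariate_map:
            r = key[1] if isinstance(key, tuple) else key
            if not 2 <= r <= R:
                raise ValueError(f"covariate map references invalid type {r}")

    def build_model(self, X: pd.DataFrame) -> TDCMModel:
        return TDCMModel.build(
            self.Q,
            T=self.T,
            n_respondents=self.I,
            X=X,
            covariate_map=self.covariate_map,
            include_interactions=self.include_interactions,
        )


def _default_q(J: int = 21, K: int = 3, multi: bool = False) -> QMatrix:
    """Single-attribute items spread evenly; optionally the last six items
    require attribute pairs (so interaction columns become active)."""
    q = np.zeros((J, K), dtype=int)
    for j in range(J):
        q[j, j % K] = 1
    if multi:
        pairs = [(0, 1), (0, 2), (1, 2)]
        for idx, j in enumerate(range(J - 6, J)):
            q[j] = 0
            for k in pairs[idx % 3]:
                q[j, k] = 1
    return QMatrix(q)


def _default_lambda(Q: QMatrix, include_interactions: bool, rng) -> ItemParams:
    from .model_core import build_item_design

    designs = build_item_design(Q, include_interactions=include_interactions)
    values = []
    for dj in designs:
        v = np.empty(dj.n_params)
        for p, (role, _) in enumerate(dj.roles):
            if role == "intercept":
                v[p] = rng.uniform(-2.0, -1.0)
            elif role == "main":
                v[p] = rng.uniform(1.5, 3.0)
            else:
                v[p] = rng.uniform(-0.5, 0.5)
        values.append(v)
    return ItemParams(values=values, time_varying=False)


def _default_gamma(K: int, T: int, covariate_map: dict, n_cov: dict, rng) -> TransitionParams:
    gamma = {}
    R = 2 ** T
    for k in range(K):
        for r in range(2, R + 1):
            p = 1 + n_cov.get((k, r), n_cov.get(r, 0))
            v = np.empty(p)
            v[0] = rng.uniform(-1.0, 1.0)
            if p > 1:
                v[1] = 1.5  # treatment slope on gain-type transitions
                v[2:] = rng.uniform(-0.5, 0.5, size=p - 2)
            gamma[(k, r)] = v
    return TransitionParams(gamma)


def _treatment_sampler(extra: str | None = None, normal_mean: float = 10.0, normal_sd: float = 2.0):
    def sample(I: int, rng) -> pd.DataFrame:
        treatment = np.zeros(I, dtype=int)
        treatment[rng.permutation(I)[: I // 2]] = 1  # balanced arms
        cols = {"treatment": treatment}
        if extra == "continuous":
            cols["cov_unif"] = rng.uniform(0.0, 1.0, size=I)
            cols["cov_norm"] = rng.normal(normal_mean, normal_sd, size=I)
        return pd.DataFrame(cols)

    return sample


def make_design(setting: int, seed: int = 0, I: int = 800, J: int = 21, K: int = 3) -> SimulationDesign:
    """Build the canonical recovery-study design for ``setting`` in 1..4."""
    if setting not in (1, 2, 3, 4):
        raise ValueError(f"unknown setting {setting!r}; expected 1, 2, 3 or 4")
    rng = np.random.default_rng(seed)
    T = 3 if setting == 4 else 2
    multi = setting == 2
    Q = _default_q(J, K, multi=multi)
    include_interactions = multi
    if setting == 4:
        # treatment between t1 and t2: applied to types whose status changes
        # across the first transition (binary trajectories 010, 011, 100, 101)
        covariate_map = {r: ["treatment"] for r in (3, 4, 5, 6)}
        sampler = _treatment_sampler()
    elif setting == 3:
        covariate_map = {2: ["treatment", "cov_unif", "cov_norm"]}
        sampler = _treatment_sampler(extra="continuous")
    else:
        covariate_map = {2: ["treatment"]}
        sampler = _treatment_sampler()
    n_cov = {r: len(v) for r, v in covariate_map.items()}
    true_lambda = _default_lambda(Q, include_interactions, rng)
    true_gamma = _default_gamma(K, T, covariate_map, n_cov, rng)
    if setting == 3:
        for k in range(K):
            # keep the large-mean normal covariate from saturating the softmax
            true_gamma.gamma[(k, 2)][2] = rng.uniform(-0.5, 0.5)
            true_gamma.gamma[(k, 2)][3] = rng.uniform(-0.1, 0.1)
    return SimulationDesign(
        I=I,
        T=T,
        Q=Q,
        true_lambda=true_lambda,
        true_gamma=true_gamma,
        covariate_map=covariate_map,
        covariate_sampler=sampler,
        include_interactions=include_interactions,
        seed=seed,
    )


def simulate_dataset(design: SimulationDesign, rng: np.random.Generator):
    """Draw covariates, trajectories, profiles, and responses.

    Returns ``(data, alpha_true, X, model)`` where ``data`` is a
    :class:`ResponseData`, ``alpha_true`` the (I, T) profile classes, ``X``
    the covariate table, and ``model`` the matching fitted-model structure.
    """
    I, T, K = design.I, design.T, design.Q.K
    X = design.covariate_sampler(I, rng)
    model = design.build_model(X)
    pcodec, tcodec = model.pcodec, model.tcodec

    bits = np.empty((I, T, K), dtype=np.int8)
    for k in range(K):
        probs = transition_type_probs(model.transition_design, design.true_gamma, k)  # (I, R)
        cum = probs.cumsum(axis=1)
        u = rng.random((I, 1))
        types = (u > cum).sum(axis=1)  # 0-based type index
        bits[:, :, k] = tcodec.all_trajectories[types]
    alpha_true = np.tensordot(bits, pcodec.weights, axes=([2], [0]))  # (I, T)

    J = design.Q.J
    Y = np.empty((I, J * T), dtype=np.int8)
    for t in range(T):
        for j, dj in enumerate(model.item_designs):
            p_class = item_response_prob(dj.delta, design.true_lambda.item_vector(j, t))
            p = p_class[alpha_true[:, t]]
            Y[:, t * J + j] = rng.random(I) < p
    data = ResponseData(Y, J=J, T=T)
    return data, alpha_true, X, model


def _truth_records(design: SimulationDesign, model: TDCMModel):
    """Flat (name, true value, block) triples aligned with PosteriorDraws."""
    attr = design.Q.attribute_names
    recs = []
    for j, dj in enumerate(model.item_designs):
        labels = dj.column_labels(attr)
        lam = design.true_lambda.item_vector(j)
        for p, lab in enumerate(labels):
            role = dj.roles[p][0]
            recs.append((f"lambda[item{j + 1},{lab}]", float(lam[p]), f"lambda_{role}"))
    for (k, r), v in sorted(design.true_gamma.gamma.items()):
        labels = model.transition_design.labels(k, r)
        for p, lab in enumerate(labels):
            block = "gamma_intercept" if lab == "intercept" else "gamma_slope"
            recs.append((f"gamma[{attr[k]},type{r},{lab}]", float(v[p]), block))
    return recs


def truth_json(design: SimulationDesign, model: TDCMModel, alpha_true: np.ndarray) -> dict:
    return {
        "seed": design.seed,
        "parameters": {name: value for name, value, _ in _truth_records(design, model)},
        "alpha_true": alpha_true.tolist(),
    }


def score_replicate(draws: PosteriorDraws, design: SimulationDesign, level: float = 0.95) -> pd.DataFrame:
    """Per-parameter truth coverage, bias, and squared error for one fit."""
    summ = draws.summary()
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    table = draws.parameter_table()
    g = table.groupby("parameter", sort=False)["value"]
    lo = g.quantile(lo_q)
    hi = g.quantile(hi_q)
    rows = []
    for name, true_val, block in _truth_records(design, draws.model):
        if name not in summ.index:
            continue
        mean = summ.loc[name, "mean"]
        rows.append(
            {
                "parameter": name,
                "block": block,
                "true": true_val,
                "mean": mean,
                "lo": lo[name],
                "hi": hi[name],
                "covered": bool(lo[name] <= true_val <= hi[name]),
                "bias": mean - true_val,
                "sq_error": (mean - true_val) ** 2,
            }
        )
    return pd.DataFrame(rows)


def replicate_study(
    design: SimulationDesign,
    n_replicates: int,
    config: SamplerConfig,
    level: float = 0.95,
    seed: int | None = None,
) -> dict:
    """Simulate-and-refit ``n_replicates`` times; report coverage/bias/RMSE.

    Each replicate gets its own simulation and chain sub-seed derived from
    ``seed`` (default: the design's seed).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    master = np.random.default_rng(design.seed if seed is None else seed)
    scored = []
    for rep in range(n_replicates):
        sim_seed, chain_seed = master.integers(2 ** 31, size=2)
        data, alpha_true, X, model = simulate_dataset(design, np.random.default_rng(sim_seed))
        rep_config = SamplerConfig(
            M=config.M,
            burn=config.burn,
            m=config.m,
            sigma_lambda=config.sigma_lambda,
            sigma_gamma=config.sigma_gamma,
            seed=int(chain_seed),
            time_constrained_lambda=config.time_constrained_lambda,
            store_alpha=False,
        )
        draws = run_gibbs(data, model, rep_config)
        table = score_replicate(draws, design, level=level)
        table["replicate"] = rep
        scored.append(table)
    all_scores = pd.concat(scored, ignore_index=True)
    per_param = all_scores.groupby("parameter", sort=False).agg(
        block=("block", "first"),
        coverage=("covered", "mean"),
        bias=("bias", "mean"),
        rmse=("sq_error", lambda s: float(np.sqrt(s.mean()))),
    )
    per_block = all_scores.groupby("block").agg(
        coverage=("covered", "mean"),
        bias=("bias", "mean"),
        rmse=("sq_error", lambda s: float(np.sqrt(s.mean()))),
    )
    return {
        "level": level,
        "n_replicates": n_replicates,
        "per_parameter": per_param,
        "per_block": per_block,
        "mean_coverage": float(all_scores["covered"].mean()),
        "lambda_coverage": float(
            all_scores.loc[all_scores["block"].str.startswith("lambda"), "covered"].mean()
        ),
        "gamma_coverage": float(
            all_scores.loc[all_scores["block"].str.startswith("gamma"), "covered"].mean()
        ),
        "raw": all_scores,
    }


def write_dataset(design: SimulationDesign, out_dir, rng: np.random.Generator) -> dict:
    """Materialize one dataset as the CSV/JSON files the fitter reads."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data, alpha_true, X, model = simulate_dataset(design, rng)
    data.to_csv(out / "responses.csv")
    design.Q.to_csv(out / "qmatrix.csv")
    X.to_csv(out / "covariates.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_json(design, model, alpha_true), fh, indent=1)
    return {
        "responses": str(out / "responses.csv"),
        "qmatrix": str(out / "qmatrix.csv"),
        "covariates": str(out / "covariates.csv"),
        "truth": str(out / "truth.json"),
        "I": design.I,
        "J": design.Q.J,
        "K": design.Q.K,
        "T": design.T,
    }
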