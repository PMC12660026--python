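"""Posterior-predictive fit checks and derived transition-probability tables.

Match percentage compares observed responses with replicate datasets
simulated from stored posterior draws; AUC (rank-based, midrank ties) and
Brier score grade predicted cell probabilities; the transition table converts
transition-regression draws into conditional mastery-change probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import softmax
from scipy.stats import rankdata

from .gibbs_engine import PosteriorDraws
from .model_core import ItemParams, ResponseData, item_response_prob

__all__ = [
    "ppc_simulate",
    "predicted_cell_probs",
    "match_percentage",
    "predictive_auc_brier",
    "transition_probability_table",
    "convergence_summary",
]


def _lambda_at_draw(draws: PosteriorDraws, d: int) -> ItemParams:
    if draws.time_varying:
        return ItemParams([draws.lambda_draws[j][d] for j in range(len(draws.lambda_draws))], True)
    return ItemParams([draws.lambda_draws[j][d] for j in range(len(draws.lambda_draws))], False)


def _cell_probs_at_draw(draws: PosteriorDraws, d: int) -> np.ndarray:
    """(I, J*T) response probabilities implied by draw d's alpha and lambda."""
    model = draws.model
    alpha = draws.alpha_draws[d]
    lam = _lambda_at_draw(draws, d)
    J, T = model.dims.J, model.dims.T
    out = np.empty((model.dims.I, J * T))
    for t in range(T):
        for j, dj in enumerate(model.item_designs):
            p_class = item_response_prob(dj.delta, lam.item_vector(j, t))
            out[:, t * J + j] = p_class[alpha[:, t]]
    return out


def ppc_simulate(draws: PosteriorDraws, n_rep: int, rng: np.random.Generator) -> np.ndarray:
    """Simulate ``n_rep`` replicate response sets from evenly spaced draws.

    Returns an (n_rep, I, J*T) binary array; replicate s is generated from
    one stored draw's profile classes and item coefficients.
    """
    if draws.alpha_draws is None:
        raise ValueError("profile draws were not stored; rerun with store_alpha=True")
    if n_rep > draws.n_draws:
        raise ValueError(f"n_rep={n_rep} exceeds stored draw count {draws.n_draws}")
    idx = np.linspace(0, draws.n_draws - 1, n_rep).round().astype(int)
    model = draws.model
    out = np.empty((n_rep, model.dims.I, model.dims.J * model.dims.T), dtype=np.int8)
    for s, d in enumerate(idx):
        p = _cell_probs_at_draw(draws, d)
        out[s] = rng.random(p.shape) < p
    return out


def predicted_cell_probs(draws: PosteriorDraws, n_rep: int | None = None) -> np.ndarray:
    """Posterior-mean (I, J*T) response probabilities over stored draws."""
    if draws.alpha_draws is None:
        raise ValueError("profile draws were not stored; rerun with store_alpha=True")
    n_rep = draws.n_draws if n_rep is None else n_rep
    idx = np.linspace(0, draws.n_draws - 1, n_rep).round().astype(int)
    acc = np.zeros((draws.model.dims.I, draws.model.dims.J * draws.model.dims.T))
    for d in idx:
        acc += _cell_probs_at_draw(draws, d)
    return acc / len(idx)


def match_percentage(data: ResponseData, replicates: np.ndarray, by: str = "item") -> pd.Series:
    """Mean percent of cells equal to the observed data, aggregated ``by``
    'item' (item-by-time), 'respondent', or 'time'."""
    Y = data.Y[None, :, :]
    if replicates.shape[1:] != data.Y.shape:
        raise ValueError("replicates must have shape (n_rep, I, J*T)")
    eq = (replicates == Y).astype(float)
    if by == "item":
        vals = eq.mean(axis=(0, 1)) * 100.0
        return pd.Series(vals, index=ResponseData.column_names(data.J, data.T), name="match_pct")
    if by == "respondent":
        return pd.Series(eq.mean(axis=(0, 2)) * 100.0, name="match_pct")
    if by == "time":
        vals = [
            eq[:, :, t * data.J : (t + 1) * data.J].mean() * 100.0 for t in range(data.T)
        ]
        return pd.Series(vals, index=[f"t{t + 1}" for t in range(data.T)], name="match_pct")
    raise ValueError("by must be 'item', 'respondent', or 'time'")


def _auc(y: np.ndarray, p: np.ndarray) -> float:
    """Rank-based AUC with midrank tie handling."""
    pos = y == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        return np.nan
    ranks = rankdata(p)
    return (ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def predictive_auc_brier(data: ResponseData, probs: np.ndarray) -> dict:
    """Per-item-per-time AUC (with min/max range per time) and per-time Brier.

    Items whose observed outcomes are all identical have no defined AUC and
    are reported as NaN (absent from the ranges), not as 0.5.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.shape != data.Y.shape:
        raise ValueError("probs must match the response matrix shape")
    if (probs <= 0).any() or (probs >= 1).any():
        raise ValueError("cell probabilities must lie strictly in (0, 1)")
    auc = np.full((data.T, data.J), np.nan)
    brier = np.empty(data.T)
    for t in range(data.T):
        block = slice(t * data.J, (t + 1) * data.J)
        Yt = data.Y[:, block]
        Pt = probs[:, block]
        for j in range(data.J):
            auc[t, j] = _auc(Yt[:, j], Pt[:, j])
        brier[t] = float(np.mean((Pt - Yt) ** 2))
    ranges = {
        f"t{t + 1}": (
            (float(np.nanmin(auc[t])), float(np.nanmax(auc[t])))
            if not np.isnan(auc[t]).all()
            else (np.nan, np.nan)
        )
        for t in range(data.T)
    }
    return {
        "auc_per_item": pd.DataFrame(
            auc.T, index=[f"item{j + 1}" for j in range(data.J)],
            columns=[f"t{t + 1}" for t in range(data.T)],
        ),
        "auc_range": ranges,
        "brier_per_time": pd.Series(brier, index=[f"t{t + 1}" for t in range(data.T)], name="brier"),
    }


def transition_probability_table(
    draws: PosteriorDraws, scenarios: dict[str, np.ndarray] | None = None
) -> dict:
    """Posterior conditional transition probabilities per attribute.

    For each covariate scenario (a single covariate row; default one all-zero
    scenario named 'baseline'), every stored draw's coefficients are turned
    into softmax type probabilities.  With T = 2 the 2x2 conditional table is
    reported: P(gain | start 0) = p2/(p1+p2) and P(loss | start 1) =
    p3/(p3+p4), with posterior means and sds.  For general T the full
    R-vector of type probabilities is summarized instead.
    """
    model = draws.model
    tdesign = model.transition_design
    K, R, T = model.dims.K, model.dims.R, model.dims.T
    if scenarios is None:
        scenarios = {"baseline": np.zeros(len(tdesign.X.columns))}
    n = draws.n_draws
    out: dict = {}
    for name, xrow in scenarios.items():
        xrow = np.asarray(xrow, dtype=float)
        per_attr = {}
        for k in range(K):
            eta = np.zeros((n, R))
            for r in range(2, R + 1):
                cols = tdesign.labels(k, r)[1:]
                xsel = np.concatenate(
                    ([1.0], [xrow[list(tdesign.X.columns).index(c)] for c in cols])
                )
                eta[:, r - 1] = draws.gamma_draws[(k, r)] @ xsel
            p = softmax(eta, axis=1)  # (n, R)
            if T == 2:
                gain = p[:, 1] / (p[:, 0] + p[:, 1])
                loss = p[:, 2] / (p[:, 2] + p[:, 3])
                per_attr[model.Q.attribute_names[k]] = pd.DataFrame(
                    {
                        "mean": [
                            1 - gain.mean(), gain.mean(), loss.mean(), 1 - loss.mean(),
                        ],
                        "sd": [gain.std(), gain.std(), loss.std(), loss.std()],
                    },
                    index=["stay0|0", "gain|0", "loss|1", "stay1|1"],
                )
            else:
                per_attr[model.Q.attribute_names[k]] = pd.DataFrame(
                    {"mean": p.mean(axis=0), "sd": p.std(axis=0)},
                    index=[f"type{r}" for r in range(1, R + 1)],
                )
        out[name] = per_attr
    return out


def render_transition_table(tables: dict) -> str:
    """Plain-text rendering, posterior sds in parentheses next to means."""
    lines = []
    for scenario, per_attr in tables.items():
        lines.append(f"scenario: {scenario}")
        for attr, tab in per_attr.items():
            lines.append(f"  {attr}")
            for label, row in tab.iterrows():
                lines.append(f"    {label:>10}: {row['mean']:.3f} ({row['sd']:.3f})")
    return "\n".join(lines)


@dataclass
class TraceFlags:
    zero_variance: bool
    drift: bool
    lag1_autocorr: float | None
    split_half_z: float | None


def convergence_summary(draws_matrix: np.ndarray | pd.DataFrame) -> pd.DataFrame:
    """Numeric trace diagnostics per parameter column.

    Reports the split-half mean discrepancy as a z-score, the lag-1
    autocorrelation, and flags constant chains and significant drift
    (|split-half z| > 4).
    """
    df = pd.DataFrame(draws_matrix)
    if len(df) < 2:
        raise ValueError("need at least two stored draws")
    rows = []
    half = len(df) // 2
    for col in df.columns:
        x = df[col].to_numpy(dtype=float)
        var = x.var()
        if var == 0:
            rows.append(
                {"parameter": col, "zero_variance": True, "drift": False,
                 "lag1_autocorr": np.nan, "split_half_z": np.nan}
            )
            continue
        a, b = x[:half], x[half:]
        # crude effective-sample-size-free z via independent-sample SEs
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        z = (b.mean() - a.mean()) / se
        ac = float(np.corrcoef(x[:-1], x[1:])[0, 1])
        rows.append(
            {"parameter": col, "zero_variance": False, "drift": bool(abs(z) > 4),
             "lag1_autocorr": ac, "split_half_z": float(z)}
        )
    return pd.DataFrame(rows).set_index("parameter")


def gof_report(
    draws: PosteriorDraws, data: ResponseData, rng: np.random.Generator, n_rep: int | None = None
) -> dict:
    """Bundle match %, AUC/Brier, and the transition table into one dict."""
    n_rep = min(draws.n_draws, 200) if n_rep is None else n_rep
    reps = ppc_simulate(draws, n_rep, rng)
    probs = predicted_cell_probs(draws, n_rep)
    # clip away exact 0/1 from degenerate draws before scoring
    probs = np.clip(probs, 1e-12, 1 - 1e-12)
    auc_brier = predictive_auc_brier(data, probs)
    # AUC range over items x individual draws (the range over items at the
    # posterior-mean probabilities is auc_range); both variants are labeled
    draw_idx = np.linspace(0, draws.n_draws - 1, min(20, draws.n_draws)).round().astype(int)
    per_draw_ranges: dict[str, list] = {f"t{t + 1}": [] for t in range(data.T)}
    for d in draw_idx:
        p_d = np.clip(_cell_probs_at_draw(draws, d), 1e-12, 1 - 1e-12)
        ab = predictive_auc_brier(data, p_d)
        for t in range(data.T):
            per_draw_ranges[f"t{t + 1}"].append(ab["auc_per_item"][f"t{t + 1}"].to_numpy())
    auc_range_x_draws = {
        key: (float(np.nanmin(vals)), float(np.nanmax(vals)))
        for key, vals in ((k, np.array(v)) for k, v in per_draw_ranges.items())
    }
    return {
        "match_by_item": match_percentage(data, reps, by="item"),
        "match_by_time": match_percentage(data, reps, by="time"),
        "match_by_respondent": match_percentage(data, reps, by="respondent"),
        "auc_range": auc_brier["auc_range"],
        "auc_range_items_x_draws": auc_range_x_draws,
        "auc_per_item": auc_brier["auc_per_item"],
        "brier_per_time": auc_brier["brier_per_time"],
        "transition_table": transition_probability_table(draws),
    }
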