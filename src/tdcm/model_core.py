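"""Domain types, codecs, design matrices, and forward probabilities.

The measurement side is a log-linear cognitive diagnosis item model: each
item's correctness probability is a logistic function of an intercept, main
effects for the attributes the item requires, and (optionally) interaction
terms for subsets of those attributes.  The structural side models each
attribute's full mastery trajectory across the ``T`` time points as one of
``2**T`` discrete transition types via a multinomial logistic regression with
respondent-level covariates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, log_softmax, softmax

__all__ = [
    "Dimensions",
    "QMatrix",
    "ProfileCodec",
    "TrajectoryCodec",
    "ItemDesign",
    "ItemParams",
    "TransitionDesign",
    "TransitionParams",
    "ResponseData",
    "ProfileState",
    "encode_profile",
    "decode_profile",
    "trajectory_to_type",
    "type_to_trajectory",
    "build_item_design",
    "item_response_prob",
    "transition_type_probs",
]

ROLE_INTERCEPT = "intercept"
ROLE_MAIN = "main"
ROLE_INTERACTION = "interaction"


@dataclass(frozen=True)
class Dimensions:
    """Problem sizes: respondents, items per time point, attributes, times."""

    I: int
    J: int
    K: int
    T: int

    def __post_init__(self) -> None:
        if self.I < 1 or self.J < 1 or self.K < 1:
            raise ValueError("I, J, K must all be >= 1")
        if self.T < 2:
            raise ValueError("T must be >= 2 (a transition needs two time points)")

    @property
    def C(self) -> int:
        """Number of attribute-profile classes, 2**K."""
        return 2 ** self.K

    @property
    def R(self) -> int:
        """Number of per-attribute trajectory types, 2**T."""
        return 2 ** self.T


class QMatrix:
    """Binary item-by-attribute alignment matrix.

    Parameters
    ----------
    q : array-like of shape (J, K)
        0/1 entries; row j marks the attributes item j requires.
    attribute_names : sequence of str, optional
        Column labels; defaults to ``attr1..attrK``.
    """

    def __init__(self, q, attribute_names: Sequence[str] | None = None):
        q = np.asarray(q)
        if q.ndim != 2:
            raise ValueError("Q-matrix must be 2-dimensional")
        if not np.isin(q, (0, 1)).all():
            raise ValueError("Q-matrix entries must be 0 or 1")
        q = q.astype(np.int8)
        if (q.sum(axis=1) == 0).any():
            bad = np.flatnonzero(q.sum(axis=1) == 0)
            raise ValueError(f"Q-matrix rows {bad.tolist()} measure no attribute")
        self.values = q
        self.J, self.K = q.shape
        if attribute_names is None:
            attribute_names = [f"attr{k + 1}" for k in range(self.K)]
        if len(attribute_names) != self.K:
            raise ValueError("attribute_names length must equal K")
        self.attribute_names = list(attribute_names)

    def required(self, j: int) -> np.ndarray:
        """Indices of the attributes item ``j`` requires."""
        return np.flatnonzero(self.values[j])

    @classmethod
    def from_csv(cls, path) -> "QMatrix":
        df = pd.read_csv(path)
        return cls(df.to_numpy(), attribute_names=list(df.columns))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, columns=self.attribute_names).to_csv(path, index=False)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, QMatrix)
            and np.array_equal(self.values, other.values)
            and self.attribute_names == other.attribute_names
        )


class ProfileCodec:
    """Bijection between binary attribute vectors and classes 0..2**K - 1.

    The first attribute is the most significant bit:
    ``c = sum_k alpha_k * 2**(K-k)`` for 1-based k.
    """

    def __init__(self, K: int):
        if K < 1:
            raise ValueError("K must be >= 1")
        self.K = K
        self.weights = 2 ** np.arange(K - 1, -1, -1)
        # all_profiles[c] is the K-bit vector of class c
        self.all_profiles = np.array(
            [[(c >> (K - 1 - k)) & 1 for k in range(K)] for c in range(2 ** K)],
            dtype=np.int8,
        )

    @property
    def n_classes(self) -> int:
        return 2 ** self.K

    def encode(self, alpha) -> int:
        alpha = np.asarray(alpha)
        if alpha.shape != (self.K,):
            raise ValueError(f"profile must have length {self.K}")
        if not np.isin(alpha, (0, 1)).all():
            raise ValueError("profile entries must be 0 or 1")
        return int(alpha @ self.weights)

    def decode(self, c: int) -> np.ndarray:
        if not 0 <= c < self.n_classes:
            raise ValueError(f"class index {c} out of range [0, {self.n_classes})")
        return self.all_profiles[c].copy()

    def has_attribute(self, c: int, k: int) -> bool:
        return bool(self.all_profiles[c, k])


class TrajectoryCodec:
    """Bijection between T-long binary mastery trajectories and types 1..2**T.

    ``r = 1 + sum_t a_t * 2**(T-t)`` (1-based t); type 1 is the all-zero,
    never-mastered trajectory used as the multinomial baseline.
    """

    def __init__(self, T: int):
        if T < 2:
            raise ValueError("T must be >= 2")
        self.T = T
        self.weights = 2 ** np.arange(T - 1, -1, -1)
        self.all_trajectories = np.array(
            [[(b >> (T - 1 - t)) & 1 for t in range(T)] for b in range(2 ** T)],
            dtype=np.int8,
        )

    @property
    def n_types(self) -> int:
        return 2 ** self.T

    def to_type(self, a) -> int:
        a = np.asarray(a)
        if a.shape != (self.T,):
            raise ValueError(f"trajectory must have length {self.T}")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("trajectory entries must be 0 or 1")
        return int(a @ self.weights) + 1

    def from_type(self, r: int) -> np.ndarray:
        if not 1 <= r <= self.n_types:
            raise ValueError(f"type {r} out of range [1, {self.n_types}]")
        return self.all_trajectories[r - 1].copy()


def encode_profile(alpha, codec: ProfileCodec) -> int:
    """Encode a binary attribute vector as its integer class index."""
    return codec.encode(alpha)


def decode_profile(c: int, codec: ProfileCodec) -> np.ndarray:
    """Inverse of :func:`encode_profile`."""
    return codec.decode(c)


def trajectory_to_type(a, codec: TrajectoryCodec) -> int:
    """Map a binary mastery trajectory to its 1-based transition type."""
    return codec.to_type(a)


def type_to_trajectory(r: int, codec: TrajectoryCodec) -> np.ndarray:
    """Inverse of :func:`trajectory_to_type`."""
    return codec.from_type(r)


@dataclass
class ItemDesign:
    """Design matrix of one item over all profile classes.

    Attributes
    ----------
    delta : (C, P) 0/1 array
        Row c is the design vector of profile class c; column p corresponds
        to one active parameter.
    roles : list of tuple
        ``("intercept", ())``, ``("main", (k,))`` or ``("interaction", (k1, k2, ...))``
        per column, attribute indices 0-based.
    lower_bounds : (P,) array
        Truncation lower bound per parameter: 0 for main effects, -inf for
        intercept and interaction terms (monotonicity via positive mains).
    """

    delta: np.ndarray
    roles: list
    lower_bounds: np.ndarray

    @property
    def n_params(self) -> int:
        return self.delta.shape[1]

    @property
    def n_classes(self) -> int:
        return self.delta.shape[0]

    def column_labels(self, attribute_names: Sequence[str] | None = None) -> list[str]:
        labels = []
        for role, subset in self.roles:
            if role == ROLE_INTERCEPT:
                labels.append("intercept")
            else:
                names = (
                    [attribute_names[k] for k in subset]
                    if attribute_names is not None
                    else [f"a{k + 1}" for k in subset]
                )
                labels.append(("main:" if role == ROLE_MAIN else "int:") + "*".join(names))
        return labels


def build_item_design(Q: QMatrix, include_interactions: bool = False) -> list[ItemDesign]:
    """Construct per-item design matrices over all 2**K profile classes.

    Columns: an intercept, one main effect per required attribute, and (when
    ``include_interactions``) one column per subset of >= 2 required
    attributes.  Entry (c, p) is 1 iff profile c possesses every attribute in
    the subset defining column p, so all-zero columns can never arise for
    subsets of required attributes.
    """
    codec = ProfileCodec(Q.K)
    profiles = codec.all_profiles  # (C, K)
    designs = []
    for j in range(Q.J):
        req = Q.required(j)
        if req.size == 0:
            raise ValueError(f"item {j} requires no attribute")
        roles: list[tuple] = [(ROLE_INTERCEPT, ())]
        cols = [np.ones(codec.n_classes, dtype=np.int8)]
        bounds = [-np.inf]
        for k in req:
            roles.append((ROLE_MAIN, (int(k),)))
            cols.append(profiles[:, k])
            bounds.append(0.0)
        if include_interactions:
            for order in range(2, req.size + 1):
                for subset in itertools.combinations(req.tolist(), order):
                    roles.append((ROLE_INTERACTION, tuple(int(k) for k in subset)))
                    cols.append(profiles[:, list(subset)].min(axis=1))
                    bounds.append(-np.inf)
        designs.append(
            ItemDesign(
                delta=np.column_stack(cols).astype(np.int8),
                roles=roles,
                lower_bounds=np.asarray(bounds, dtype=float),
            )
        )
    return designs


@dataclass
class ItemParams:
    """Item coefficients on the logit scale, one vector per item.

    In time-varying mode ``values[j]`` has shape (T, P_j); in the default
    time-constrained mode it is a flat (P_j,) vector shared across time.
    """

    values: list[np.ndarray]
    time_varying: bool = False

    def item_vector(self, j: int, t: int = 0) -> np.ndarray:
        v = self.values[j]
        return v[t] if self.time_varying else v


def item_response_prob(delta, lam) -> np.ndarray | float:
    """Correct-response probability sigma(delta . lambda) for given class rows."""
    delta = np.asarray(delta, dtype=float)
    lam = np.asarray(lam, dtype=float)
    eta = delta @ lam
    return expit(eta)


class TransitionDesign:
    """Per-attribute, per-type covariate design for the transition model.

    Each non-baseline type r (2..R) gets an intercept plus the covariate
    columns named in ``covariate_map[(k, r)]`` (or ``covariate_map[r]`` when
    shared across attributes).  The baseline type r = 1 carries no parameters.
    """

    def __init__(
        self,
        X: pd.DataFrame | None,
        K: int,
        T: int,
        covariate_map: Mapping | None = None,
        n_respondents: int | None = None,
    ):
        self.K = K
        self.T = T
        self.R = 2 ** T
        if X is None:
            if n_respondents is None:
                raise ValueError("n_respondents required when no covariates given")
            X = pd.DataFrame(index=range(n_respondents))
        if not all(np.issubdtype(dt, np.number) for dt in X.dtypes):
            raise ValueError("covariate columns must be numeric")
        self.X = X.reset_index(drop=True)
        self.I = len(self.X)
        self.covariate_map = dict(covariate_map or {})
        self._designs: dict[tuple[int, int], np.ndarray] = {}
        self._labels: dict[tuple[int, int], list[str]] = {}
        ones = np.ones((self.I, 1))
        for k in range(K):
            for r in range(2, self.R + 1):
                names = self._columns_for(k, r)
                missing = [n for n in names if n not in self.X.columns]
                if missing:
                    raise ValueError(f"unknown covariate columns {missing} for attribute {k}, type {r}")
                mat = (
                    np.hstack([ones, self.X[names].to_numpy(dtype=float)])
                    if names
                    else ones.copy()
                )
                self._designs[(k, r)] = mat
                self._labels[(k, r)] = ["intercept"] + list(names)

    def _columns_for(self, k: int, r: int) -> list[str]:
        if (k, r) in self.covariate_map:
            return list(self.covariate_map[(k, r)])
        if r in self.covariate_map:
            return list(self.covariate_map[r])
        return []

    def design(self, k: int, r: int) -> np.ndarray:
        """(I, 1 + n_cov) design matrix for attribute k, type r (r >= 2)."""
        if r == 1:
            raise ValueError("baseline type 1 carries no parameters")
        return self._designs[(k, r)]

    def n_params(self, k: int, r: int) -> int:
        return self._designs[(k, r)].shape[1]

    def labels(self, k: int, r: int) -> list[str]:
        return self._labels[(k, r)]


@dataclass
class TransitionParams:
    """Multinomial-logit coefficients gamma[(k, r)] for non-baseline types."""

    gamma: dict

    @classmethod
    def zeros(cls, design: TransitionDesign) -> "TransitionParams":
        return cls(
            {
                (k, r): np.zeros(design.n_params(k, r))
                for k in range(design.K)
                for r in range(2, design.R + 1)
            }
        )

    def copy(self) -> "TransitionParams":
        return TransitionParams({key: v.copy() for key, v in self.gamma.items()})


def transition_linear_predictors(
    design: TransitionDesign, params: TransitionParams, k: int
) -> np.ndarray:
    """(I, R) matrix of linear predictors for attribute k; baseline column 0."""
    eta = np.zeros((design.I, design.R))
    for r in range(2, design.R + 1):
        eta[:, r - 1] = design.design(k, r) @ params.gamma[(k, r)]
    if not np.isfinite(eta).all():
        raise FloatingPointError("non-finite transition linear predictor")
    return eta


def transition_type_probs(
    design: TransitionDesign, params: TransitionParams, k: int, log: bool = False
) -> np.ndarray:
    """Per-respondent softmax probabilities over the R trajectory types."""
    eta = transition_linear_predictors(design, params, k)
    return log_softmax(eta, axis=1) if log else softmax(eta, axis=1)


class ResponseData:
    """Binary response matrix of shape (I, J*T) with a per-column time index.

    Columns are ordered time-major: item j at time t lives at column
    ``(t-1)*J + (j-1)`` and is named ``item<j>_t<t>`` (1-based labels).
    """

    def __init__(self, Y, J: int, T: int):
        Y = np.asarray(Y)
        if Y.ndim != 2 or Y.shape[1] != J * T:
            raise ValueError(f"expected {J * T} response columns, got {Y.shape}")
        if pd.isna(Y.astype(float)).any():
            raise ValueError("missing responses are not supported")
        if not np.isin(Y, (0, 1)).all():
            raise ValueError("responses must be 0 or 1 with no missing cells")
        self.Y = Y.astype(np.int8)
        self.I = Y.shape[0]
        self.J = J
        self.T = T
        self.time_of_column = np.repeat(np.arange(T), J)

    def block(self, t: int) -> np.ndarray:
        """(I, J) responses at 0-based time t."""
        return self.Y[:, t * self.J : (t + 1) * self.J]

    @staticmethod
    def column_names(J: int, T: int) -> list[str]:
        return [f"item{j + 1}_t{t + 1}" for t in range(T) for j in range(J)]

    @classmethod
    def from_csv(cls, path, J: int | None = None, T: int | None = None) -> "ResponseData":
        df = pd.read_csv(path)
        if df.isna().any().any():
            raise ValueError("missing responses are not supported")
        names = list(df.columns)
        if J is None or T is None:
            items, times = set(), set()
            for name in names:
                stem, _, tpart = name.partition("_t")
                if not (stem.startswith("item") and tpart.isdigit()):
                    raise ValueError(f"unparseable response column name {name!r}")
                items.add(int(stem[4:]))
                times.add(int(tpart))
            J, T = max(items), max(times)
        expected = cls.column_names(J, T)
        if names != expected:
            raise ValueError("response columns must be named item<j>_t<t> in time-major order")
        return cls(df.to_numpy(), J=J, T=T)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.Y, columns=self.column_names(self.J, self.T)).to_csv(path, index=False)


@dataclass
class ProfileState:
    """Current profile class indices, shape (I, T), values in 0..2**K - 1."""

    alpha: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=np.int64)
        if self.alpha.ndim != 2:
            raise ValueError("alpha must be (I, T)")
        if self.alpha.min() < 0 or self.alpha.max() >= 2 ** self.K:
            raise ValueError("profile class index out of range")

    def attribute_bits(self, codec: ProfileCodec) -> np.ndarray:
        """(I, T, K) binary mastery indicators."""
        return codec.all_profiles[self.alpha]

    def trajectory_types(self, pcodec: ProfileCodec, tcodec: TrajectoryCodec) -> np.ndarray:
        """(I, K) 1-based trajectory type of every respondent and attribute."""
        bits = self.attribute_bits(pcodec)  # (I, T, K)
        return np.tensordot(bits, tcodec.weights, axes=([1], [0])) + 1
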