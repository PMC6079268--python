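"""Comparison link predictors: Katz index, a CATAPULT-style walk-count PU
learner, and plain masked matrix factorization.

Katz scores a node pair by the attenuated count of walks of every length
between them, S = sum_{l=1..K} beta^l A^l, on the unweighted untyped
adjacency.  The CATAPULT-style learner turns per-length walk counts between
drug-gene pairs into features and fits a class-weighted logistic scorer
against negatives sampled uniformly from the unlabeled pairs (positive-
unlabeled strategy).  Plain MF is mask-aware alternating ridge least squares
on the interaction matrix, the no-kernel comparator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import scipy.sparse
from sklearn.linear_model import LogisticRegression

from .hetnet import HetNet, NodeLookupError
from .kbmf import InteractionMatrix

__all__ = [
    "KatzConfig",
    "WalkCountFeatures",
    "LinearScorer",
    "MFResult",
    "katz_scores",
    "catapult_features",
    "catapult_train",
    "mf_fit",
]


@dataclass(frozen=True)
class KatzConfig:
    beta: float = 0.01
    max_walk_length: int = 4

    def __post_init__(self) -> None:
        if not (0.0 < self.beta < 1.0):
            raise ValueError(f"attenuation beta={self.beta} outside (0, 1)")
        if self.max_walk_length < 1:
            raise ValueError("max_walk_length must be >= 1")


def _adjacency(net: HetNet) -> Tuple[List[str], scipy.sparse.csr_matrix]:
    ids = net.node_ids()
    index = {n: i for i, n in enumerate(ids)}
    rows, cols = [], []
    for a, b, _rel, _w in net.edges():
        rows += [index[a], index[b]]
        cols += [index[b], index[a]]
    data = np.ones(len(rows))
    A = scipy.sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(ids), len(ids))
    )
    A.data[:] = 1.0  # binarize parallel relations
    A.sum_duplicates()
    A.data[:] = np.minimum(A.data, 1.0)
    return ids, A


def katz_scores(net: HetNet, cfg: KatzConfig) -> Tuple[List[str], np.ndarray]:
    """Truncated Katz similarity over all node pairs.

    Returns (ids, S) with S = sum_{l=1..K} beta^l A^l on the binary untyped
    adjacency; symmetric because A is.
    """
    if net.num_nodes == 0:
        raise ValueError("empty network")
    ids, A = _adjacency(net)
    Ad = A.toarray()
    S = np.zeros_like(Ad)
    P = np.eye(len(ids))
    for ell in range(1, cfg.max_walk_length + 1):
        P = P @ Ad
        S += cfg.beta ** ell * P
    return ids, S


@dataclass
class WalkCountFeatures:
    """Per drug-gene pair, the number of heterogeneous walks of length 1..L."""

    pairs: List[Tuple[str, str]]
    counts: np.ndarray  # (n_pairs, L)

    @property
    def max_length(self) -> int:
        return self.counts.shape[1]

    def rows(self, pairs: Sequence[Tuple[str, str]]) -> np.ndarray:
        index = {p: i for i, p in enumerate(self.pairs)}
        try:
            return self.counts[[index[p] for p in pairs]]
        except KeyError as exc:
            raise NodeLookupError(f"pair {exc.args[0]!r} has no features") from None


def catapult_features(
    net: HetNet, pairs: Sequence[Tuple[str, str]], L: int
) -> WalkCountFeatures:
    """Walk counts (A^l)[drug, gene] for l = 1..L on the full heterogeneous adjacency."""
    if L < 1:
        raise ValueError("L must be >= 1")
    ids, A = _adjacency(net)
    index = {n: i for i, n in enumerate(ids)}
    for d, g in pairs:
        if d not in index:
            raise NodeLookupError(d)
        if g not in index:
            raise NodeLookupError(g)
    rows = np.array([index[d] for d, _ in pairs])
    cols = np.array([index[g] for _, g in pairs])
    counts = np.zeros((len(pairs), L))
    P = A.copy()
    for ell in range(L):
        if ell > 0:
            P = P @ A
        counts[:, ell] = np.asarray(P[rows, cols]).ravel()
    return WalkCountFeatures(pairs=list(pairs), counts=counts)


@dataclass
class LinearScorer:
    """Logistic scorer over walk-count features; score = w . x + b."""

    weights: np.ndarray
    intercept: float

    def score(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(features) @ self.weights + self.intercept

    def to_json(self) -> dict:
        return {"weights": self.weights.tolist(), "intercept": self.intercept}


def catapult_train(
    features: WalkCountFeatures,
    positives: Sequence[Tuple[str, str]],
    unlabeled: Sequence[Tuple[str, str]],
    ratio: float = 1.0,
    seed: int = 0,
    C: float = 1.0,
) -> LinearScorer:
    """PU training: sample provisional negatives uniformly from the unlabeled
    pool, then fit an L2-regularized logistic scorer with positives up-weighted
    by the sampling ratio.
    """
    positives = sorted(set(positives))
    unlabeled = sorted(set(unlabeled))
    if not positives:
        raise ValueError("need at least one positive pair")
    if ratio <= 0:
        raise ValueError("negatives-per-positive ratio must be positive")
    n_neg = int(round(ratio * len(positives)))
    if n_neg > len(unlabeled):
        raise ValueError(
            f"unlabeled pool of {len(unlabeled)} cannot supply {n_neg} negatives"
        )
    rng = np.random.default_rng(seed)
    neg_idx = rng.choice(len(unlabeled), size=n_neg, replace=False)
    negatives = [unlabeled[i] for i in sorted(neg_idx)]

    Xmat = np.vstack([features.rows(positives), features.rows(negatives)])
    y = np.concatenate([np.ones(len(positives)), np.zeros(n_neg)])
    clf = LogisticRegression(
        C=C, class_weight={1: max(ratio, 1.0), 0: 1.0}, max_iter=2000
    )
    clf.fit(Xmat, y)
    return LinearScorer(
        weights=clf.coef_.ravel().copy(), intercept=float(clf.intercept_[0])
    )


@dataclass
class MFResult:
    """Masked-ALS factorization Y ~ U V^T with its objective trace."""

    U: np.ndarray
    V: np.ndarray
    objective_trace: List[float]

    def score_matrix(self) -> np.ndarray:
        return self.U @ self.V.T


def mf_fit(
    Y: InteractionMatrix,
    rank: int,
    reg: float = 0.01,
    iters: int = 100,
    seed: int = 0,
) -> MFResult:
    """Alternating ridge least squares on the masked interaction matrix.

    Minimizes ||mask o (Y - U V^T)||_F^2 + reg (||U||^2 + ||V||^2); each row
    update is the exact conditional minimizer, so the objective trace is
    non-increasing.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    mask = Y.mask.astype(float)
    if not mask.any():
        raise ValueError("empty observation mask: no training data")
    Yv = Y.values
    Nd, Ng = Yv.shape
    rng = np.random.default_rng(seed)
    U = rng.standard_normal((Nd, rank)) * 0.1
    V = rng.standard_normal((Ng, rank)) * 0.1

    def objective() -> float:
        R = mask * (Yv - U @ V.T)
        return float(np.sum(R ** 2) + reg * (np.sum(U ** 2) + np.sum(V ** 2)))

    trace = [objective()]
    eye = np.eye(rank)
    for _ in range(iters):
        for i in range(Nd):
            w = mask[i]
            G = (V * w[:, None]).T @ V + reg * eye
            U[i] = np.linalg.solve(G, V.T @ (w * Yv[i]))
        for j in range(Ng):
            w = mask[:, j]
            G = (U * w[:, None]).T @ U + reg * eye
            V[j] = np.linalg.solve(G, U.T @ (w * Yv[:, j]))
        trace.append(objective())
    return MFResult(U=U, V=V, objective_trace=trace)
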