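"""Kernelized Bayesian matrix factorization for drug-gene pair scoring.

Each side (drugs, genes) carries one or more kernels — here Gram matrices of
metapath embedding vectors, optionally augmented with similarity matrices.
Projection matrices A_d (N_d x X) and A_g (N_g x X) map kernel columns into a
shared X-dimensional subspace; per-kernel components G^m = A^T K^m are mixed
by unconstrained Gaussian-prior kernel weights e into composite components
H_d = sum_m e_d[m] G_d^m and H_g, and the score of a drug-gene pair is the
bilinear product H_d^T H_g.

Inference is MAP alternating optimization: each block (A_d, e_d, A_g, e_g) is
set to the exact minimizer of the penalized weighted squared-error objective

    L = sum_ij W_ij (Y_ij - S_ij)^2 + lambda (||A_d||^2 + ||A_g||^2 + ...)

given the others, so the objective trace is non-increasing by construction.
Observed interactions get unit weight; 0-entries inside the observation mask
are weak negatives with a down-weighting factor (positive-unlabeled reading);
entries outside the mask do not enter the loss at all.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.linalg

from .hetnet import HetNet, NodeLookupError, NodeType, RelationType
from .skipgram import EmbeddingModel

__all__ = [
    "KernelSet",
    "InteractionMatrix",
    "KbmfModel",
    "kernels_from_embeddings",
    "kernel_from_similarity",
    "kbmf_fit",
    "kbmf_score",
    "load_kbmf_model",
]

_PSD_TOL = -1e-8
_JITTER = 1e-8


@dataclass
class KernelSet:
    """Symmetric PSD kernels over a fixed ordering of one side's nodes."""

    side: str  # "drug" or "gene"
    ids: List[str]
    kernels: List[np.ndarray]

    def __post_init__(self) -> None:
        if self.side not in ("drug", "gene"):
            raise ValueError(f"side must be 'drug' or 'gene', got {self.side!r}")
        n = len(self.ids)
        if not self.kernels:
            raise ValueError("kernel set needs at least one kernel")
        for K in self.kernels:
            if K.shape != (n, n):
                raise ValueError(f"kernel shape {K.shape} does not match {n} ids")
            if not np.allclose(K, K.T, atol=1e-8):
                raise ValueError("kernel not symmetric")
            if scipy.linalg.eigvalsh(K, subset_by_index=[0, 0])[0] < _PSD_TOL:
                raise ValueError("kernel not PSD (min eigenvalue below -1e-8)")

    @property
    def num_kernels(self) -> int:
        return len(self.kernels)


def kernels_from_embeddings(
    models: Sequence[EmbeddingModel],
    side: str,
    kind: str = "linear",
    ids: Optional[Sequence[str]] = None,
    missing: str = "error",
) -> KernelSet:
    """One kernel per embedding model from that side's input vectors.

    kind "linear" gives the Gram matrix E E^T of the side's vectors; "cosine"
    row-normalizes first (unit diagonal).  A small diagonal jitter keeps the
    kernels numerically PSD.

    Nodes missing from a model raise a coverage error by default;
    ``missing="zero"`` assigns them zero vectors instead (isolated nodes in a
    training split never enter any walk).
    """
    if kind not in ("linear", "cosine"):
        raise ValueError(f"unknown kernel kind {kind!r}")
    node_type = NodeType.DRUG if side == "drug" else NodeType.GENE
    if ids is None:
        ids = sorted(models[0].type_index[node_type])
    ids = list(ids)
    if not ids:
        raise ValueError(f"no {side} nodes to build kernels over")
    kernels = []
    for model in models:
        E = np.zeros((len(ids), model.dimension))
        for i, nid in enumerate(ids):
            if nid in model.index:
                E[i] = model.input_vector(nid)
            elif missing == "error":
                raise NodeLookupError(
                    f"{side} node {nid!r} missing from embedding model"
                )
        if kind == "cosine":
            norms = np.linalg.norm(E, axis=1, keepdims=True)
            E = np.divide(E, norms, out=np.zeros_like(E), where=norms > 0)
        K = E @ E.T
        if kind == "cosine":
            np.fill_diagonal(K, 1.0)
        K = K + _JITTER * np.eye(len(ids))
        kernels.append(K)
    return KernelSet(side=side, ids=ids, kernels=kernels)


def kernel_from_similarity(values: np.ndarray, ids: Sequence[str], side: str) -> KernelSet:
    """Wrap a similarity matrix as a kernel, jittered onto the PSD cone."""
    K = np.asarray(values, dtype=float)
    w = scipy.linalg.eigvalsh(K, subset_by_index=[0, 0])[0]
    if w < 0:
        K = K + (abs(w) + _JITTER) * np.eye(K.shape[0])
    else:
        K = K + _JITTER * np.eye(K.shape[0])
    return KernelSet(side=side, ids=list(ids), kernels=[K])


@dataclass
class InteractionMatrix:
    """Drug x gene interaction indicators with an observation mask.

    values[i, j] = 1 for a known interaction, 0 for unknown; mask marks the
    training entries — held-out test pairs are excluded from the mask.
    """

    drug_ids: List[str]
    gene_ids: List[str]
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.drug_ids), len(self.gene_ids))
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != shape or self.mask.shape != shape:
            raise ValueError("values/mask shape does not match id lists")

    @classmethod
    def from_hetnet(
        cls,
        net: HetNet,
        drug_ids: Optional[Sequence[str]] = None,
        gene_ids: Optional[Sequence[str]] = None,
        exclude_pairs: Optional[Sequence[Tuple[str, str]]] = None,
    ) -> "InteractionMatrix":
        drug_ids = list(drug_ids) if drug_ids is not None else net.nodes_of_type(NodeType.DRUG)
        gene_ids = list(gene_ids) if gene_ids is not None else net.nodes_of_type(NodeType.GENE)
        di = {d: i for i, d in enumerate(drug_ids)}
        gi = {g: i for i, g in enumerate(gene_ids)}
        values = np.zeros((len(drug_ids), len(gene_ids)))
        for a, b, _rel, _w in net.edges(RelationType.DRUG_GENE):
            if a in di and b in gi:
                values[di[a], gi[b]] = 1.0
        mask = np.ones_like(values, dtype=bool)
        for d, g in exclude_pairs or ():
            if d in di and g in gi:
                mask[di[d], gi[g]] = False
        return cls(drug_ids=drug_ids, gene_ids=gene_ids, values=values, mask=mask)


@dataclass
class KbmfModel:
    """Fitted projections, kernel weights and composite components."""

    drug_ids: List[str]
    gene_ids: List[str]
    A_d: np.ndarray  # (N_d, X)
    A_g: np.ndarray  # (N_g, X)
    e_d: np.ndarray  # (M,)
    e_g: np.ndarray  # (N,)
    G_d: List[np.ndarray]  # per-kernel components, each (X, N_d)
    G_g: List[np.ndarray]
    H_d: np.ndarray  # (X, N_d)
    H_g: np.ndarray  # (X, N_g)
    X: int
    objective_trace: List[float]

    @property
    def iterations(self) -> int:
        return len(self.objective_trace)

    def score_matrix(self) -> np.ndarray:
        return self.H_d.T @ self.H_g

    def save(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)

        def dump(name, arr, row_ids=None):
            with open(os.path.join(directory, name), "w", encoding="utf-8") as fh:
                for i, row in enumerate(np.atleast_2d(arr)):
                    prefix = f"{row_ids[i]}\t" if row_ids is not None else ""
                    fh.write(prefix + "\t".join(f"{v:.17g}" for v in row) + "\n")

        dump("A_d.tsv", self.A_d, self.drug_ids)
        dump("A_g.tsv", self.A_g, self.gene_ids)
        dump("H_d.tsv", self.H_d.T, self.drug_ids)
        dump("H_g.tsv", self.H_g.T, self.gene_ids)
        meta = {
            "X": self.X,
            "e_d": self.e_d.tolist(),
            "e_g": self.e_g.tolist(),
            "iterations": self.iterations,
            "final_objective": self.objective_trace[-1] if self.objective_trace else None,
            "drug_ids": self.drug_ids,
            "gene_ids": self.gene_ids,
        }
        with open(os.path.join(directory, "meta.json"), "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2)


def load_kbmf_model(directory) -> KbmfModel:
    """Reload a checkpoint written by :meth:`KbmfModel.save`.

    Projection matrices and composite components are restored; per-kernel
    components are not serialized and come back empty.
    """
    with open(os.path.join(directory, "meta.json"), "r", encoding="utf-8") as fh:
        meta = json.load(fh)

    def read(name):
        ids, rows = [], []
        with open(os.path.join(directory, name), "r", encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return ids, np.array(rows)

    _, A_d = read("A_d.tsv")
    _, A_g = read("A_g.tsv")
    _, H_d_T = read("H_d.tsv")
    _, H_g_T = read("H_g.tsv")
    final = meta.get("final_objective")
    return KbmfModel(
        drug_ids=meta["drug_ids"], gene_ids=meta["gene_ids"],
        A_d=A_d, A_g=A_g,
        e_d=np.asarray(meta["e_d"], dtype=float),
        e_g=np.asarray(meta["e_g"], dtype=float),
        G_d=[], G_g=[], H_d=H_d_T.T, H_g=H_g_T.T,
        X=int(meta["X"]),
        objective_trace=[final] if final is not None else [],
    )


def _weights(Y: InteractionMatrix, zero_weight: float) -> np.ndarray:
    W = np.where(Y.values > 0, 1.0, zero_weight)
    W[~Y.mask] = 0.0
    return W


def _solve_projection(
    C: np.ndarray, H_other: np.ndarray, W: np.ndarray, Y: np.ndarray,
    prior_prec: float, X: int,
) -> np.ndarray:
    """Exact minimizer over A of sum_ij W_ij (Y_ij - c_i^T A h_j)^2 + lam ||A||^2.

    C is the weighted kernel mix (N x N, symmetric, c_i its i-th column);
    H_other (X x N_other) holds the opposite side's composite components.
    Solved as one ridge least-squares in vec(A) (column-major), exploiting
    sum_i W_ij c_i c_i^T = C diag(W_:,j) C.
    """
    N = C.shape[0]
    M = np.zeros((N * X, N * X))
    for j in range(H_other.shape[1]):
        h = H_other[:, j]
        wcol = W[:, j]
        if not wcol.any():
            continue
        CWC = (C * wcol) @ C  # C diag(w) C^T with C symmetric
        M += np.kron(np.outer(h, h), CWC)
    M[np.diag_indices_from(M)] += prior_prec
    R = C @ (W * Y) @ H_other.T  # (N, X)
    b = scipy.linalg.solve(M, R.reshape(-1, order="F"), assume_a="pos")
    return b.reshape(N, X, order="F")


def _solve_weights(
    G: List[np.ndarray], H_other: np.ndarray, W: np.ndarray, Y: np.ndarray,
    prior_prec: float,
) -> np.ndarray:
    """Exact ridge minimizer over kernel weights e of the same objective."""
    T = [g.T @ H_other for g in G]  # each (N, N_other)
    m = len(T)
    A = np.empty((m, m))
    rhs = np.empty(m)
    for p in range(m):
        rhs[p] = np.sum(W * Y * T[p])
        for q in range(p, m):
            A[p, q] = A[q, p] = np.sum(W * T[p] * T[q])
    A[np.diag_indices_from(A)] += prior_prec
    return scipy.linalg.solve(A, rhs, assume_a="pos")


def kbmf_fit(
    Kd: KernelSet,
    Kg: KernelSet,
    Y: InteractionMatrix,
    X: int,
    iters: int = 200,
    seed: int = 0,
    prior_prec: float = 1.0,
    noise_prec: float = 1.0,
    zero_weight: float = 0.1,
    fix_weights: bool = False,
) -> KbmfModel:
    """MAP alternating optimization of the kernelized factorization.

    Updates A_d, e_d, A_g, e_g in turn, each to its exact conditional
    minimizer, starting from a seeded Gaussian initialization; the penalized
    objective is therefore non-increasing across iterations.  With
    ``fix_weights=True`` the kernel weights stay at 1 (and drop out of the
    prior term), which with single identity kernels reduces the model to plain
    masked matrix factorization.
    """
    if Kd.ids != Y.drug_ids or Kg.ids != Y.gene_ids:
        raise ValueError("kernel id orderings must match the interaction matrix")
    Nd, Ng = len(Y.drug_ids), len(Y.gene_ids)
    if X < 1 or X > min(Nd, Ng):
        raise ValueError(f"subspace dimension X={X} outside [1, min(N_d, N_g)]")
    if not Y.mask.any():
        raise ValueError("empty observation mask: no training data")

    W = noise_prec * _weights(Y, zero_weight)
    Yv = Y.values
    rng = np.random.default_rng(seed)
    A_d = rng.standard_normal((Nd, X)) * 0.1
    A_g = rng.standard_normal((Ng, X)) * 0.1
    e_d = np.ones(Kd.num_kernels)
    e_g = np.ones(Kg.num_kernels)

    def mixes():
        C_d = sum(e * K for e, K in zip(e_d, Kd.kernels))
        C_g = sum(e * K for e, K in zip(e_g, Kg.kernels))
        return C_d, C_g

    def objective() -> float:
        C_d, C_g = mixes()
        S = (C_d @ A_d) @ (C_g @ A_g).T
        val = float(np.sum(W * (Yv - S) ** 2))
        val += prior_prec * (np.sum(A_d ** 2) + np.sum(A_g ** 2))
        if not fix_weights:
            val += prior_prec * (np.sum(e_d ** 2) + np.sum(e_g ** 2))
        return val

    trace = [objective()]
    for _ in range(iters):
        C_d, C_g = mixes()
        H_g = (C_g @ A_g).T  # (X, Ng)
        A_d = _solve_projection(C_d, H_g, W, Yv, prior_prec, X)
        if not fix_weights:
            G_d = [(A_d.T @ K) for K in Kd.kernels]  # (X, Nd) each
            e_d = _solve_weights(G_d, H_g, W, Yv, prior_prec)
            C_d = sum(e * K for e, K in zip(e_d, Kd.kernels))
        H_d = (C_d @ A_d).T  # (X, Nd)
        A_g = _solve_projection(C_g, H_d, W.T, Yv.T, prior_prec, X)
        if not fix_weights:
            G_g = [(A_g.T @ K) for K in Kg.kernels]
            e_g = _solve_weights(G_g, H_d, W.T, Yv.T, prior_prec)
        trace.append(objective())

    C_d, C_g = mixes()
    G_d = [A_d.T @ K for K in Kd.kernels]
    G_g = [A_g.T @ K for K in Kg.kernels]
    H_d = sum(e * G for e, G in zip(e_d, G_d))
    H_g = sum(e * G for e, G in zip(e_g, G_g))
    return KbmfModel(
        drug_ids=list(Y.drug_ids), gene_ids=list(Y.gene_ids),
        A_d=A_d, A_g=A_g, e_d=np.asarray(e_d, dtype=float),
        e_g=np.asarray(e_g, dtype=float),
        G_d=G_d, G_g=G_g, H_d=H_d, H_g=H_g, X=X, objective_trace=trace,
    )


def kbmf_score(
    model: KbmfModel, drugs: Sequence[str], genes: Sequence[str]
) -> np.ndarray:
    """Submatrix of the bilinear score matrix H_d^T H_g for the given ids."""
    di = {d: i for i, d in enumerate(model.drug_ids)}
    gi = {g: i for i, g in enumerate(model.gene_ids)}
    try:
        rows = [di[d] for d in drugs]
    except KeyError as exc:
        raise NodeLookupError(f"unknown drug {exc.args[0]!r}") from None
    try:
        cols = [gi[g] for g in genes]
    except KeyError as exc:
        raise NodeLookupError(f"unknown gene {exc.args[0]!r}") from None
    S = model.H_d.T @ model.H_g
    return S[np.ix_(rows, cols)]
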