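"""Heterogeneous skip-gram training: softmax, hierarchical softmax, NCE,
negative sampling, and the metapath2vec / metapath2vec++ trainers.

The model keeps two vector tables: an input ("center") vector v_d and an
output ("context") vector v'_d per vocabulary node.  The probability of a
context node g given a center node d under the full softmax is

    p(g | d) = exp(v'_g . v_d) / sum_x exp(v'_x . v_d).

Training maximizes the average log probability of the contexts observed in a
metapath walk corpus within a symmetric window of radius c, using negative
sampling: each observed (center, context) pair is contrasted against k nodes
drawn from a unigram^0.75 noise distribution.  metapath2vec draws those
negatives from the global vocabulary; metapath2vec++ draws them only from
nodes of the context node's type, using per-type noise distributions, which
makes the implicit normalization type-specific.

Noise-contrastive estimation treats the unnormalized score p_theta = exp(v'.v)
and discriminates data from noise via

    p(label=1 | g, d) = p_theta / (p_theta + k q(g)),

which reduces to the logistic sigmoid of the inner product when k q(g) = 1 —
the negative-sampling special case.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .hetnet import HetNet, HetlinkError, NodeLookupError, NodeType
from .walks import WalkCorpus

logger = logging.getLogger("hetlink")

__all__ = [
    "EmbeddingModel",
    "TrainConfig",
    "NoiseModel",
    "TrainingInstance",
    "HuffmanTree",
    "softmax_prob",
    "softmax_all",
    "skipgram_objective",
    "build_huffman_tree",
    "hierarchical_softmax_prob",
    "nce_loss",
    "nce_instance_loss_and_grad",
    "sgns_instance_loss_and_grad",
    "negative_sampling_update",
    "heterogeneous_objective",
    "train",
]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


# --------------------------------------------------------------------- model

class EmbeddingModel:
    """Per-node input and output vectors of dimension d, typed vocabulary."""

    def __init__(
        self,
        ids: Sequence[str],
        types: Mapping[str, NodeType],
        in_vecs: np.ndarray,
        out_vecs: np.ndarray,
    ) -> None:
        self.ids = list(ids)
        self.index = {nid: i for i, nid in enumerate(self.ids)}
        self.types = {nid: NodeType(types[nid]) for nid in self.ids}
        self.in_vecs = np.asarray(in_vecs, dtype=float)
        self.out_vecs = np.asarray(out_vecs, dtype=float)
        if self.in_vecs.shape != self.out_vecs.shape:
            raise ValueError("input/output tables must share shape")
        if self.in_vecs.shape[0] != len(self.ids):
            raise ValueError("vector table does not cover the vocabulary")

    @property
    def dimension(self) -> int:
        return self.in_vecs.shape[1]

    @property
    def vocab_size(self) -> int:
        return len(self.ids)

    @property
    def type_index(self) -> Dict[NodeType, List[str]]:
        out: Dict[NodeType, List[str]] = {t: [] for t in NodeType}
        for nid in self.ids:
            out[self.types[nid]].append(nid)
        return out

    def _idx(self, node: str) -> int:
        try:
            return self.index[node]
        except KeyError:
            raise NodeLookupError(node) from None

    def input_vector(self, node: str) -> np.ndarray:
        return self.in_vecs[self._idx(node)]

    def output_vector(self, node: str) -> np.ndarray:
        return self.out_vecs[self._idx(node)]

    @classmethod
    def init_random(
        cls,
        vocabulary: Mapping[str, Tuple[NodeType, int]],
        dimension: int,
        seed: int = 0,
    ) -> "EmbeddingModel":
        """Both tables drawn uniformly from [-0.5/d, 0.5/d]."""
        ids = sorted(vocabulary)
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0]))
        shape = (len(ids), dimension)
        in_vecs = (rng.random(shape) - 0.5) / dimension
        out_vecs = (rng.random(shape) - 0.5) / dimension
        types = {nid: vocabulary[nid][0] for nid in ids}
        return cls(ids=ids, types=types, in_vecs=in_vecs, out_vecs=out_vecs)

    # word2vec text format + sidecar type table -----------------------------

    def save(self, path, types_path=None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{self.vocab_size} {self.dimension}\n")
            for nid in self.ids:
                vec = " ".join(f"{v:.17g}" for v in self.in_vecs[self.index[nid]])
                fh.write(f"{nid} {vec}\n")
        if types_path is not None:
            with open(types_path, "w", encoding="utf-8") as fh:
                for nid in self.ids:
                    fh.write(f"{nid}\t{self.types[nid].value}\n")

    @classmethod
    def load(cls, path, types_path) -> "EmbeddingModel":
        types: Dict[str, NodeType] = {}
        with open(types_path, "r", encoding="utf-8") as fh:
            for line in fh:
                nid, t = line.rstrip("\n").split("\t")
                types[nid] = NodeType(t)
        ids, rows = [], []
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline().split()
            n, d = int(header[0]), int(header[1])
            for line in fh:
                parts = line.split()
                ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        vecs = np.array(rows, dtype=float)
        if vecs.shape != (n, d):
            raise ValueError(f"embedding file promises {(n, d)}, read {vecs.shape}")
        # output vectors are not serialized; reload as zeros
        return cls(ids=ids, types=types, in_vecs=vecs, out_vecs=np.zeros_like(vecs))


@dataclass(frozen=True)
class TrainConfig:
    """Skip-gram training hyperparameters.

    window is the symmetric context radius c; negatives the number k of noise
    samples per observed pair; learning_rate decays linearly to 1e-4 of its
    initial value over all training windows.
    """

    dimension: int = 100
    window: int = 2
    negatives: int = 5
    epochs: int = 5
    learning_rate: float = 0.025
    seed: int = 0
    mode: str = "metapath2vecpp"  # or "metapath2vec"

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.negatives < 1:
            raise ValueError("negatives must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.mode not in ("metapath2vec", "metapath2vecpp"):
            raise ValueError(f"unknown mode {self.mode!r}")


class NoiseModel:
    """Unigram^power noise distribution q, globally and per node type."""

    def __init__(
        self,
        distribution: Mapping[str, float],
        types: Mapping[str, NodeType],
    ) -> None:
        total = float(sum(distribution.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"noise distribution sums to {total}, not 1")
        self.distribution: Dict[str, float] = dict(sorted(distribution.items()))
        self.types = {nid: NodeType(types[nid]) for nid in self.distribution}
        self.per_type: Dict[NodeType, Dict[str, float]] = {}
        for t in NodeType:
            sub = {
                nid: p for nid, p in self.distribution.items()
                if self.types[nid] is t
            }
            s = sum(sub.values())
            if s > 0:
                self.per_type[t] = {nid: p / s for nid, p in sub.items()}
        # sampling tables
        self._global_ids = list(self.distribution)
        self._global_cum = np.cumsum([self.distribution[i] for i in self._global_ids])
        self._type_ids: Dict[NodeType, List[str]] = {}
        self._type_cum: Dict[NodeType, np.ndarray] = {}
        for t, sub in self.per_type.items():
            ids = list(sub)
            self._type_ids[t] = ids
            self._type_cum[t] = np.cumsum([sub[i] for i in ids])

    @classmethod
    def from_corpus(cls, corpus: WalkCorpus, power: float = 0.75) -> "NoiseModel":
        if not corpus.vocabulary:
            raise ValueError("empty corpus has no noise distribution")
        weights = {nid: freq ** power for nid, (_, freq) in corpus.vocabulary.items()}
        total = sum(weights.values())
        dist = {nid: w / total for nid, w in weights.items()}
        types = {nid: t for nid, (t, _) in corpus.vocabulary.items()}
        return cls(distribution=dist, types=types)

    def q(self, node: str) -> float:
        p = self.distribution.get(node)
        if p is None or p <= 0.0:
            raise NodeLookupError(f"{node!r} outside noise support")
        return p

    def table(self, node_type: Optional[NodeType] = None):
        """(ids, cumulative probabilities) for global or per-type sampling."""
        if node_type is None:
            return self._global_ids, self._global_cum
        t = NodeType(node_type)
        if t not in self._type_ids:
            raise NodeLookupError(f"no nodes of type {t.value} in noise support")
        return self._type_ids[t], self._type_cum[t]

    def sample(self, rng: np.random.Generator, k: int,
               node_type: Optional[NodeType] = None) -> List[str]:
        ids, cum = self.table(node_type)
        idx = np.minimum(
            np.searchsorted(cum, rng.random(k), side="right"), len(ids) - 1
        )
        return [ids[i] for i in idx]


@dataclass(frozen=True)
class TrainingInstance:
    """One (center, candidate) labelled example against the center's context set."""

    center: str
    true_context: FrozenSet[str]
    candidate: str
    label: int

    def __post_init__(self) -> None:
        expected = 1 if self.candidate in self.true_context else 0
        if self.label != expected:
            raise ValueError(
                f"label {self.label} inconsistent with membership of "
                f"{self.candidate!r} in the true context set"
            )


# ------------------------------------------------------------- full softmax

def softmax_all(center: str, model: EmbeddingModel) -> np.ndarray:
    """Softmax distribution over the whole vocabulary for one center node."""
    logits = model.out_vecs @ model.input_vector(center)
    logits -= logits.max()  # stability
    e = np.exp(logits)
    return e / e.sum()


def softmax_prob(center: str, context: str, model: EmbeddingModel) -> float:
    """p(context | center) under the full softmax over the vocabulary."""
    return float(softmax_all(center, model)[model._idx(context)])


def skipgram_objective(corpus: WalkCorpus, model: EmbeddingModel, c: int) -> float:
    """Average log probability of in-window contexts over the corpus.

    The window of radius c is clipped at walk boundaries; the average is over
    the N corpus tokens. Always <= 0.
    """
    if not corpus.walks or corpus.num_tokens == 0:
        raise ValueError("objective undefined on an empty corpus")
    if c < 1:
        raise ValueError("window must be >= 1")
    total = 0.0
    n_tokens = 0
    for walk in corpus.walks:
        L = len(walk)
        n_tokens += L
        for n, center in enumerate(walk):
            dist = softmax_all(center, model)
            logd = np.log(dist)
            for j in range(max(0, n - c), min(L, n + c + 1)):
                if j != n:
                    total += logd[model._idx(walk[j])]
    return total / n_tokens


# ------------------------------------------------------ hierarchical softmax

@dataclass
class HuffmanTree:
    """Binary Huffman code over the vocabulary with trainable internal vectors.

    codes[leaf] is the root-to-leaf bit sequence (left = 1, right = 0);
    paths[leaf] the matching internal-node indices into internal_vectors.
    """

    leaf_ids: List[str]
    codes: Dict[str, Tuple[int, ...]]
    paths: Dict[str, Tuple[int, ...]]
    internal_vectors: np.ndarray

    @property
    def num_internal(self) -> int:
        return self.internal_vectors.shape[0]


def build_huffman_tree(
    frequencies: Mapping[str, float],
    dimension: int,
    seed: Optional[int] = None,
) -> HuffmanTree:
    """Build a Huffman tree from vocabulary frequencies.

    Internal vectors start at zero (every branch probability 1/2) unless a
    seed is given, in which case they are drawn uniformly from
    [-0.5/d, 0.5/d].
    """
    ids = sorted(frequencies)
    if not ids:
        raise ValueError("cannot build a Huffman tree over an empty vocabulary")
    n_internal = max(len(ids) - 1, 0)
    if seed is None:
        internal = np.zeros((n_internal, dimension))
    else:
        rng = np.random.default_rng(seed)
        internal = (rng.random((n_internal, dimension)) - 0.5) / dimension

    if len(ids) == 1:
        return HuffmanTree(
            leaf_ids=ids, codes={ids[0]: ()}, paths={ids[0]: ()},
            internal_vectors=internal,
        )

    # heap items: (frequency, tiebreak, payload); payload is a leaf id or an
    # (internal index, left payload, right payload) triple
    heap: list = []
    for order, nid in enumerate(ids):
        heapq.heappush(heap, (float(frequencies[nid]), order, nid))
    counter = len(ids)
    internal_idx = 0
    while len(heap) > 1:
        f1, _, left = heapq.heappop(heap)
        f2, _, right = heapq.heappop(heap)
        heapq.heappush(heap, (f1 + f2, counter, (internal_idx, left, right)))
        counter += 1
        internal_idx += 1

    codes: Dict[str, Tuple[int, ...]] = {}
    paths: Dict[str, Tuple[int, ...]] = {}

    def assign(payload, bits: Tuple[int, ...], nodes: Tuple[int, ...]) -> None:
        if isinstance(payload, str):
            codes[payload] = bits
            paths[payload] = nodes
            return
        idx, left, right = payload
        assign(left, bits + (1,), nodes + (idx,))
        assign(right, bits + (0,), nodes + (idx,))

    assign(heap[0][2], (), ())
    return HuffmanTree(
        leaf_ids=ids, codes=codes, paths=paths, internal_vectors=internal
    )


def hierarchical_softmax_prob(
    center: str, context: str, tree: HuffmanTree, model: EmbeddingModel
) -> float:
    """p(context | center) as a product of branch sigmoids along the Huffman path.

    Going left (bit 1) at internal node n has probability sigmoid(w_n . v_center);
    going right the complement. Probabilities over all leaves sum to 1.
    """
    if context not in tree.codes:
        raise NodeLookupError(context)
    v = model.input_vector(center)
    prob = 1.0
    for bit, idx in zip(tree.codes[context], tree.paths[context]):
        s = float(tree.internal_vectors[idx] @ v)
        prob *= _sigmoid(s) if bit == 1 else _sigmoid(-s)
    return float(prob)


# ------------------------------------------------------------ NCE and SGNS

def _ptheta(model: EmbeddingModel, center: str, candidate: str) -> float:
    return float(np.exp(model.output_vector(candidate) @ model.input_vector(center)))


def nce_true_prob(
    model: EmbeddingModel, noise: NoiseModel, k: int, center: str, candidate: str
) -> float:
    """p(label=1 | candidate, center) = p_theta / (p_theta + k q(candidate))."""
    p = _ptheta(model, center, candidate)
    return p / (p + k * noise.q(candidate))


def nce_loss(
    instances: Sequence[TrainingInstance],
    model: EmbeddingModel,
    noise: NoiseModel,
    k: int,
) -> float:
    """Mean NCE log-likelihood over center observations.

    Each label-1 instance is one center observation; the value is

        (1/N) [ sum_{label=1} log p(1|g,d) + sum_{label=0} log p(0|g,d) ]

    with p(1) = p_theta/(p_theta + k q) and p(0) its complement, N the number
    of label-1 instances.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_pos = sum(1 for inst in instances if inst.label == 1)
    if n_pos == 0:
        raise ValueError("need at least one positive instance")
    total = 0.0
    for inst in instances:
        p1 = nce_true_prob(model, noise, k, inst.center, inst.candidate)
        total += np.log(p1) if inst.label == 1 else np.log1p(-p1)
    return float(total / n_pos)


def nce_instance_loss_and_grad(
    model: EmbeddingModel,
    noise: NoiseModel,
    k: int,
    center: str,
    positive: str,
    negatives: Sequence[str],
):
    """NCE log-likelihood of one center observation and its analytic gradient.

    Returns (loss, grad_in, grad_out) where grad_in is the gradient w.r.t. the
    center's input vector and grad_out maps node id -> gradient w.r.t. that
    node's output vector (ascent direction).
    """
    v = model.input_vector(center)
    grad_in = np.zeros_like(v)
    grad_out: Dict[str, np.ndarray] = {}
    loss = 0.0

    def accumulate(node: str, is_positive: bool) -> None:
        nonlocal loss, grad_in
        p = _ptheta(model, center, node)
        kq = k * noise.q(node)
        p1 = p / (p + kq)
        if is_positive:
            loss += np.log(p1)
            coeff = 1.0 - p1  # d log p1 / d s
        else:
            loss += np.log1p(-p1)
            coeff = -p1  # d log (1-p1) / d s
        out = model.output_vector(node)
        grad_in += coeff * out
        grad_out[node] = grad_out.get(node, 0.0) + coeff * v

    accumulate(positive, True)
    for neg in negatives:
        accumulate(neg, False)
    return float(loss), grad_in, grad_out


def sgns_instance_loss_and_grad(
    model: EmbeddingModel,
    center: str,
    positive: str,
    negatives: Sequence[str],
):
    """Negative-sampling log-likelihood of one pair and its analytic gradient.

    loss = log sigmoid(v'_pos . v) + sum_neg log sigmoid(-v'_neg . v); the
    special case of NCE with k q(.) = 1, where p(1) = p_theta/(p_theta+1).
    """
    v = model.input_vector(center)
    grad_in = np.zeros_like(v)
    grad_out: Dict[str, np.ndarray] = {}

    s_pos = float(model.output_vector(positive) @ v)
    p_pos = float(_sigmoid(s_pos))
    loss = float(np.log(p_pos))
    grad_in += (1.0 - p_pos) * model.output_vector(positive)
    grad_out[positive] = (1.0 - p_pos) * v

    for neg in negatives:
        s = float(model.output_vector(neg) @ v)
        p = float(_sigmoid(s))
        loss += float(np.log1p(-p))
        grad_in += -p * model.output_vector(neg)
        grad_out[neg] = grad_out.get(neg, 0.0) + (-p) * v
    return loss, grad_in, grad_out


_MAX_REDRAWS = 100


def _draw_negatives(
    noise: NoiseModel,
    rng: np.random.Generator,
    k: int,
    exclude: FrozenSet[str] | set,
    node_type: Optional[NodeType],
) -> Optional[List[str]]:
    """k noise samples avoiding ``exclude``; None if redraws are exhausted."""
    ids, cum = noise.table(node_type)
    out: List[str] = []
    attempts = 0
    while len(out) < k:
        need = k - len(out)
        idx = np.minimum(
            np.searchsorted(cum, rng.random(need), side="right"), len(ids) - 1
        )
        for i in idx:
            cand = ids[i]
            if cand not in exclude:
                out.append(cand)
        attempts += 1
        if attempts > _MAX_REDRAWS:
            return None
    return out


def negative_sampling_update(
    inst: TrainingInstance,
    model: EmbeddingModel,
    noise: NoiseModel,
    k: int,
    lr: float,
    rng: np.random.Generator,
    node_type: Optional[NodeType] = None,
) -> EmbeddingModel:
    """One stochastic-gradient ascent step on the negative-sampling objective.

    Draws k negatives from the noise distribution (per-type when ``node_type``
    is given), redrawing any that hit the true context set; after 100 failed
    redraw rounds the instance is skipped with a log message.  Only the
    center's input vector and the sampled nodes' output vectors change.
    """
    if lr <= 0:
        raise ValueError("learning rate must be positive")
    negatives = _draw_negatives(noise, rng, k, inst.true_context, node_type)
    if negatives is None:
        logger.warning(
            "skipping instance for center %r: negative redraw limit reached",
            inst.center,
        )
        return model
    _, grad_in, grad_out = sgns_instance_loss_and_grad(
        model, inst.center, inst.candidate, negatives
    )
    model.in_vecs[model._idx(inst.center)] += lr * grad_in
    for nid, g in grad_out.items():
        model.out_vecs[model._idx(nid)] += lr * g
    return model


# --------------------------------------------------- heterogeneous objective

def heterogeneous_objective(net: HetNet, model: EmbeddingModel) -> float:
    """Sum over nodes, neighbor types and typed neighbors of log p(neighbor|node).

    Diagnostic value of the heterogeneous skip-gram objective on the network
    itself (each undirected edge contributes one term per endpoint).
    """
    total = 0.0
    for d in net.node_ids():
        dist = None
        for t in NodeType:
            for g, _w in net.typed_neighbors(d, t):
                if dist is None:
                    dist = np.log(softmax_all(d, model))
                total += dist[model._idx(g)]
    return float(total)


# ------------------------------------------------------------------ training

def train(
    corpus: WalkCorpus,
    cfg: TrainConfig,
    noise: Optional[NoiseModel] = None,
    negative_callback: Optional[Callable[[str, str, List[str]], None]] = None,
) -> EmbeddingModel:
    """Train an embedding on a walk corpus with negative sampling.

    mode "metapath2vec" draws negatives from the global noise distribution;
    mode "metapath2vecpp" restricts them to the context node's type.  Training
    is single-threaded and bit-deterministic given the seed.

    ``negative_callback(center, context, negatives)``, if given, observes every
    drawn negative set (instrumentation hook for tests).
    """
    if not corpus.walks or corpus.num_tokens == 0:
        raise ValueError("cannot train on an empty corpus")
    if len(corpus.vocabulary) == 1 and cfg.negatives >= 1:
        raise ValueError("degenerate vocabulary of size 1: nothing to contrast")

    model = EmbeddingModel.init_random(corpus.vocabulary, cfg.dimension, cfg.seed)
    if cfg.epochs == 0:
        return model
    if noise is None:
        noise = NoiseModel.from_corpus(corpus)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 1]))
    per_type = cfg.mode == "metapath2vecpp"

    total_windows = cfg.epochs * corpus.num_tokens
    lr0 = cfg.learning_rate
    lr_floor = lr0 * 1e-4
    step = 0

    in_vecs, out_vecs = model.in_vecs, model.out_vecs
    index = model.index
    for _epoch in range(cfg.epochs):
        for walk in corpus.walks:
            L = len(walk)
            for n, center in enumerate(walk):
                lr = max(lr0 * (1.0 - step / total_windows), lr_floor)
                step += 1
                ci = index[center]
                v = in_vecs[ci]
                lo, hi = max(0, n - cfg.window), min(L, n + cfg.window + 1)
                for j in range(lo, hi):
                    if j == n:
                        continue
                    context = walk[j]
                    t = model.types[context] if per_type else None
                    negatives = _draw_negatives(
                        noise, rng, cfg.negatives, {context}, t
                    )
                    if negatives is None:
                        logger.warning(
                            "skipping pair (%r, %r): redraw limit", center, context
                        )
                        continue
                    if negative_callback is not None:
                        negative_callback(center, context, negatives)
                    rows = [index[context]] + [index[x] for x in negatives]
                    outs = out_vecs[rows]  # (k+1, d) copy
                    s = outs @ v
                    p = _sigmoid(s)
                    coeff = np.empty_like(p)
                    coeff[0] = 1.0 - p[0]
                    coeff[1:] = -p[1:]
                    grad_in = coeff @ outs
                    np.add.at(out_vecs, rows, (lr * coeff)[:, None] * v)
                    in_vecs[ci] = v = v + lr * grad_in
    return model
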