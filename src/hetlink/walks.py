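"""Metapath parsing and metapath-constrained random-walk corpus generation.

A metapath is a cyclic sequence of node types, e.g. Drug-ADR-Drug-Gene-Drug:
the walker starts on a node of the first type and at each step moves to a
uniformly chosen (or weight-proportional) neighbor whose type is the next one
in the scheme, wrapping around when the scheme is exhausted.  Walks that reach
a node with no neighbor of the required type are truncated there, so every
emitted walk is a valid prefix of the type pattern.

Each (start node, walker) pair gets its own deterministic random substream
derived from the global seed, making corpora reproducible and independent of
generation order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .hetnet import HetNet, HetlinkError, NodeType

__all__ = [
    "Metapath",
    "WalkConfig",
    "WalkCorpus",
    "MetapathParseError",
    "parse_metapath",
    "generate_walks",
]


class MetapathParseError(HetlinkError, ValueError):
    """Unknown node type or non-recursive scheme."""


@dataclass(frozen=True)
class Metapath:
    """Cyclic sequence of node types guiding a constrained random walk."""

    types: Tuple[NodeType, ...]

    def __post_init__(self) -> None:
        if len(self.types) < 2:
            raise MetapathParseError("metapath needs at least two types")
        if self.types[0] is not self.types[-1]:
            raise MetapathParseError(
                "metapath must start and end with the same type so it can be "
                f"applied recursively; got {self.types[0].value} ... "
                f"{self.types[-1].value}"
            )

    @property
    def period(self) -> int:
        return len(self.types) - 1

    def type_at(self, position: int) -> NodeType:
        """Node type required at 0-based walk position, cyclically extended."""
        return self.types[position % self.period]

    def __str__(self) -> str:
        return "-".join(t.value.upper() if t is NodeType.ADR else t.value.capitalize()
                        for t in self.types)


_TYPE_ALIASES = {
    "drug": NodeType.DRUG,
    "gene": NodeType.GENE,
    "adr": NodeType.ADR,
}


def parse_metapath(scheme: str) -> Metapath:
    """Parse a dash-separated scheme such as ``"Drug-ADR-Drug-Gene-Drug"``.

    Type names are case-insensitive. The scheme must return to its first type.
    """
    parts = [p.strip() for p in scheme.replace("–", "-").split("-")]
    types = []
    for p in parts:
        t = _TYPE_ALIASES.get(p.lower())
        if t is None:
            raise MetapathParseError(f"unknown node type {p!r} in scheme {scheme!r}")
        types.append(t)
    return Metapath(types=tuple(types))


@dataclass(frozen=True)
class WalkConfig:
    """w walkers per start node, walks of at most l tokens."""

    num_walkers_per_start: int = 10
    walk_length: int = 20
    seed: int = 0
    weighted: bool = False

    def __post_init__(self) -> None:
        if self.num_walkers_per_start < 1:
            raise ValueError("num_walkers_per_start must be >= 1")
        if self.walk_length < 2:
            raise ValueError("walk_length must be >= 2")


@dataclass
class WalkCorpus:
    """Random-walk token sequences plus the induced typed vocabulary."""

    walks: List[List[str]]
    vocabulary: Dict[str, Tuple[NodeType, int]]

    @property
    def num_tokens(self) -> int:
        return sum(len(w) for w in self.walks)

    def save(self, path) -> None:
        """One walk per line, space-separated node ids (word2vec corpus format)."""
        with open(path, "w", encoding="utf-8") as fh:
            for walk in self.walks:
                fh.write(" ".join(walk) + "\n")

    @classmethod
    def load(cls, path, net: HetNet) -> "WalkCorpus":
        walks = []
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                tokens = line.split()
                if tokens:
                    walks.append(tokens)
        return cls(walks=walks, vocabulary=_build_vocabulary(walks, net))


def _build_vocabulary(
    walks: Sequence[Sequence[str]], net: HetNet
) -> Dict[str, Tuple[NodeType, int]]:
    freq: Dict[str, int] = {}
    for walk in walks:
        for tok in walk:
            freq[tok] = freq.get(tok, 0) + 1
    vocab = {}
    for tok in sorted(freq):
        if tok not in net.nodes:
            raise KeyError(f"corpus token {tok!r} not a network node")
        vocab[tok] = (net.nodes[tok], freq[tok])
    return vocab


def generate_walks(net: HetNet, mp: Metapath, cfg: WalkConfig) -> WalkCorpus:
    """Generate ``w`` metapath-constrained walks from every start-type node.

    Transition at walk position ``i`` goes to a neighbor of type
    ``mp.type_at(i + 1)``, chosen uniformly at random, or proportionally to
    edge weight when ``cfg.weighted``.  Dead ends truncate the walk.
    """
    starts = net.nodes_of_type(mp.types[0])
    if not starts:
        warnings.warn(
            f"no node of start type {mp.types[0].value}; returning empty corpus",
            stacklevel=2,
        )
        return WalkCorpus(walks=[], vocabulary={})

    # Pre-index typed neighbors once: node -> type -> (ids array, cumprob array)
    tables: Dict[str, Dict[NodeType, Tuple[List[str], np.ndarray]]] = {}
    for node in net.node_ids():
        per_type = {}
        for t in NodeType:
            nbrs = net.typed_neighbors(node, t)
            if nbrs:
                ids = [n for n, _ in nbrs]
                if cfg.weighted:
                    w = np.array([max(wt, 0.0) for _, wt in nbrs], dtype=float)
                    total = w.sum()
                    probs = w / total if total > 0 else np.full(len(ids), 1 / len(ids))
                else:
                    probs = np.full(len(ids), 1.0 / len(ids))
                per_type[t] = (ids, np.cumsum(probs))
        tables[node] = per_type

    walks: List[List[str]] = []
    for start_idx, start in enumerate(starts):
        for walker_idx in range(cfg.num_walkers_per_start):
            rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, start_idx, walker_idx])
            )
            walk = [start]
            node = start
            while len(walk) < cfg.walk_length:
                want = mp.type_at(len(walk))
                entry = tables[node].get(want)
                if entry is None:
                    break  # dead end: truncate
                ids, cum = entry
                idx = min(
                    int(np.searchsorted(cum, rng.random(), side="right")),
                    len(ids) - 1,
                )
                node = ids[idx]
                walk.append(node)
            walks.append(walk)

    return WalkCorpus(walks=walks, vocabulary=_build_vocabulary(walks, net))
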