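"""Typed heterogeneous drug-gene-ADR network: data model, I/O and similarity edges.

The network couples three node types (drugs, genes, adverse drug reactions)
through four undirected relation types: drug-drug similarity, gene-gene
similarity, drug-gene interaction, and drug-ADR causality.  Similarity
relations carry weights in [0, 1]; interaction/causality edges carry arbitrary
nonnegative weights (1.0 for plain presence).

Node identifiers are opaque strings in a single namespace.  Every operation
that returns a list of nodes or edges returns it in sorted order so that all
downstream randomized procedures are reproducible from their seeds alone.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Set, Tuple

import numpy as np

logger = logging.getLogger("hetlink")

__all__ = [
    "NodeType",
    "RelationType",
    "HetNet",
    "SimilarityMatrix",
    "HetlinkError",
    "EdgelistParseError",
    "SchemaError",
    "NodeLookupError",
    "load_edgelist",
    "write_edgelist",
    "atc_similarity",
    "sparsify_similarity",
    "typed_neighbors",
]


class HetlinkError(Exception):
    """Base class for all package errors."""


class EdgelistParseError(HetlinkError, ValueError):
    """A malformed row in an edge-list file; message names the line."""


class SchemaError(HetlinkError, ValueError):
    """Edge endpoints violate the node types demanded by the relation."""


class NodeLookupError(HetlinkError, KeyError):
    """A node id is unknown to the network or model."""


class NodeType(str, enum.Enum):
    DRUG = "drug"
    GENE = "gene"
    ADR = "adr"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class RelationType(str, enum.Enum):
    DRUG_DRUG_SIM = "drug_drug_sim"
    GENE_GENE_SIM = "gene_gene_sim"
    DRUG_GENE = "drug_gene"
    DRUG_ADR = "drug_adr"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: endpoint types demanded by each relation (unordered for same-type relations,
#: canonical order (drug, other) for mixed relations)
RELATION_ENDPOINTS: Dict[RelationType, Tuple[NodeType, NodeType]] = {
    RelationType.DRUG_DRUG_SIM: (NodeType.DRUG, NodeType.DRUG),
    RelationType.GENE_GENE_SIM: (NodeType.GENE, NodeType.GENE),
    RelationType.DRUG_GENE: (NodeType.DRUG, NodeType.GENE),
    RelationType.DRUG_ADR: (NodeType.DRUG, NodeType.ADR),
}

#: similarity relations must have weights in [0, 1]
SIMILARITY_RELATIONS = frozenset(
    {RelationType.DRUG_DRUG_SIM, RelationType.GENE_GENE_SIM}
)


class HetNet:
    """Undirected heterogeneous multigraph with typed nodes and typed edges.

    At most one edge per (node pair, relation); re-adding an existing edge
    keeps the maximum weight, so similarity evidence from multiple sources
    never sums above 1.
    """

    def __init__(self) -> None:
        self.nodes: Dict[str, NodeType] = {}
        # canonical key -> weight; key = (a, b, rel) with endpoints ordered
        self._edges: Dict[Tuple[str, str, RelationType], float] = {}
        # node -> NodeType -> {neighbor: weight} (collapsed over relations, max)
        self._adj: Dict[str, Dict[NodeType, Dict[str, float]]] = {}

    # ------------------------------------------------------------------ build

    def add_node(self, node_id: str, node_type: NodeType) -> None:
        node_type = NodeType(node_type)
        existing = self.nodes.get(node_id)
        if existing is not None and existing is not node_type:
            raise SchemaError(
                f"node {node_id!r} already registered as {existing.value}, "
                f"cannot re-register as {node_type.value}"
            )
        self.nodes[node_id] = node_type
        self._adj.setdefault(node_id, {t: {} for t in NodeType})

    def _canonical_key(
        self, a: str, b: str, rel: RelationType
    ) -> Tuple[str, str, RelationType]:
        ta, tb = self.nodes[a], self.nodes[b]
        want = RELATION_ENDPOINTS[rel]
        if want[0] is want[1]:
            if not (ta is want[0] and tb is want[0]):
                raise SchemaError(
                    f"relation {rel.value} requires two {want[0].value} nodes, "
                    f"got {ta.value}/{tb.value} for ({a!r}, {b!r})"
                )
            a, b = sorted((a, b))
        else:
            if ta is want[1] and tb is want[0]:
                a, b = b, a
                ta, tb = tb, ta
            if not (ta is want[0] and tb is want[1]):
                raise SchemaError(
                    f"relation {rel.value} requires a ({want[0].value}, "
                    f"{want[1].value}) pair, got {ta.value}/{tb.value} "
                    f"for ({a!r}, {b!r})"
                )
        return a, b, rel

    def add_edge(self, a: str, b: str, rel: RelationType, weight: float = 1.0) -> None:
        rel = RelationType(rel)
        if a not in self.nodes:
            raise NodeLookupError(a)
        if b not in self.nodes:
            raise NodeLookupError(b)
        if a == b:
            raise SchemaError(f"self-loop on {a!r} not allowed")
        weight = float(weight)
        if weight < 0:
            raise SchemaError(f"negative edge weight {weight} on ({a!r}, {b!r})")
        if rel in SIMILARITY_RELATIONS and not (0.0 <= weight <= 1.0):
            raise SchemaError(
                f"similarity weight {weight} outside [0, 1] on ({a!r}, {b!r})"
            )
        key = self._canonical_key(a, b, rel)
        old = self._edges.get(key)
        if old is not None:
            weight = max(old, weight)  # duplicate collapse rule
        self._edges[key] = weight
        ka, kb, _ = key
        self._adj[ka][self.nodes[kb]][kb] = weight
        self._adj[kb][self.nodes[ka]][ka] = weight

    def remove_edge(self, a: str, b: str, rel: RelationType) -> None:
        key = self._canonical_key(a, b, rel)
        if key not in self._edges:
            raise NodeLookupError(f"edge {key} not present")
        del self._edges[key]
        ka, kb, _ = key
        # only drop adjacency if no other relation still links the pair
        if not any(
            k in self._edges for k in (self._canonical_key(ka, kb, r)
                                       for r in self._relations_between(ka, kb))
        ):
            self._adj[ka][self.nodes[kb]].pop(kb, None)
            self._adj[kb][self.nodes[ka]].pop(ka, None)

    def _relations_between(self, a: str, b: str) -> Iterator[RelationType]:
        ta, tb = self.nodes[a], self.nodes[b]
        pair = frozenset((ta, tb)) if ta is not tb else frozenset((ta,))
        for rel, want in RELATION_ENDPOINTS.items():
            wpair = frozenset(want)
            if wpair == pair:
                yield rel

    # ------------------------------------------------------------------ query

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    @property
    def num_nodes(self) -> int:
        return len(self.nodes)

    @property
    def num_edges(self) -> int:
        return len(self._edges)

    def node_ids(self) -> List[str]:
        return sorted(self.nodes)

    def nodes_of_type(self, t: NodeType) -> List[str]:
        t = NodeType(t)
        return sorted(n for n, nt in self.nodes.items() if nt is t)

    def edges(
        self, rel: RelationType | None = None
    ) -> List[Tuple[str, str, RelationType, float]]:
        """All edges as (src, dst, relation, weight), deterministically sorted."""
        items = (
            (a, b, r, w)
            for (a, b, r), w in self._edges.items()
            if rel is None or r is rel
        )
        return sorted(items, key=lambda e: (e[2].value, e[0], e[1]))

    def has_edge(self, a: str, b: str, rel: RelationType) -> bool:
        try:
            return self._canonical_key(a, b, rel) in self._edges
        except SchemaError:
            return False

    def typed_neighbors(self, node: str, t: NodeType) -> List[Tuple[str, float]]:
        """Neighbors of ``node`` having type ``t``, sorted by id."""
        if node not in self.nodes:
            raise NodeLookupError(node)
        return sorted(self._adj[node][NodeType(t)].items())

    def neighbors(self, node: str) -> List[Tuple[str, float]]:
        if node not in self.nodes:
            raise NodeLookupError(node)
        out: Dict[str, float] = {}
        for t in NodeType:
            out.update(self._adj[node][t])
        return sorted(out.items())

    def copy(self) -> "HetNet":
        dup = HetNet()
        dup.nodes = dict(self.nodes)
        dup._edges = dict(self._edges)
        dup._adj = {
            n: {t: dict(d) for t, d in by_type.items()}
            for n, by_type in self._adj.items()
        }
        return dup


def typed_neighbors(net: HetNet, node: str, t: NodeType) -> List[Tuple[str, float]]:
    """Module-level alias for :meth:`HetNet.typed_neighbors`."""
    return net.typed_neighbors(node, t)


# ---------------------------------------------------------------------- I/O

_EDGE_COLUMNS = ("src_id", "src_type", "dst_id", "dst_type", "relation", "weight")


def load_edgelist(path, strict: bool = True) -> HetNet:
    """Read a 6-column TSV edge list into a :class:`HetNet`.

    Columns: src_id, src_type, dst_id, dst_type, relation, weight.  Lines
    starting with ``#`` and blank lines are ignored; an optional header row
    repeating the column names is skipped.  Duplicate edges collapse keeping
    the maximum weight.

    With ``strict=True`` a relation/type mismatch raises :class:`SchemaError`;
    otherwise the offending row is skipped with a log message.
    """
    net = HetNet()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and tuple(p.strip() for p in parts) == _EDGE_COLUMNS:
                continue
            if len(parts) != 6:
                raise EdgelistParseError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, "
                    f"got {len(parts)}"
                )
            src, src_t, dst, dst_t, rel_s, w_s = (p.strip() for p in parts)
            try:
                st, dt = NodeType(src_t), NodeType(dst_t)
                rel = RelationType(rel_s)
                weight = float(w_s)
            except ValueError as exc:
                raise EdgelistParseError(f"{path}:{lineno}: {exc}") from exc
            try:
                net.add_node(src, st)
                net.add_node(dst, dt)
                net.add_edge(src, dst, rel, weight)
            except SchemaError as exc:
                if strict:
                    raise SchemaError(f"{path}:{lineno}: {exc}") from exc
                logger.warning("skipping %s:%d: %s", path, lineno, exc)
    return net


def write_edgelist(net: HetNet, path) -> None:
    """Write the network in the same 6-column TSV format read by load_edgelist."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_EDGE_COLUMNS) + "\n")
        for a, b, rel, w in net.edges():
            fh.write(
                f"{a}\t{net.nodes[a].value}\t{b}\t{net.nodes[b].value}"
                f"\t{rel.value}\t{w:.17g}\n"
            )


# ------------------------------------------------------------- similarity

@dataclass
class SimilarityMatrix:
    """Symmetric similarity scores in [0, 1] with unit diagonal."""

    ids: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"similarity matrix shape {self.values.shape} does not match "
                f"{n} ids"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix not symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-12):
            raise ValueError("similarity matrix diagonal not 1")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("similarity values outside [0, 1]")

    def lookup(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, a in enumerate(self.ids):
                row = "\t".join(f"{v:.17g}" for v in self.values[i])
                fh.write(f"{a}\t{row}\n")

    @classmethod
    def from_tsv(cls, path) -> "SimilarityMatrix":
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            ids = header[1:]
            rows = []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                rows.append([float(x) for x in parts[1:]])
        return cls(ids=ids, values=np.array(rows))


# ATC code: letter, 2 digits, letter, letter, 2 digits (5 levels, 7 chars)
_ATC_RE = re.compile(r"^[A-Z][0-9]{2}[A-Z][A-Z][0-9]{2}$")
#: cumulative character lengths of the 5 ATC levels
ATC_LEVEL_ENDS = (1, 3, 4, 5, 7)


def _atc_shared_levels(x: str, y: str) -> int:
    shared = 0
    for end in ATC_LEVEL_ENDS:
        if x[:end] == y[:end]:
            shared += 1
        else:
            break
    return shared


def atc_similarity(codes: Mapping[str, Set[str] | Iterable[str]]) -> SimilarityMatrix:
    """Pharmacological drug similarity from WHO ATC classification codes.

    For two drugs the score is the best agreement over all their code pairs:
    the number of consecutive shared leading ATC levels divided by 5.  A drug
    is always similarity 1 to itself.

    Raises ``ValueError`` for codes that do not decompose into the five
    standard levels (1/2/1/1/2 characters) and for drugs with no codes.
    """
    ids = sorted(codes)
    norm: Dict[str, List[str]] = {}
    for d in ids:
        cs = sorted(set(codes[d]))
        if not cs:
            raise ValueError(f"drug {d!r} has no ATC codes")
        for c in cs:
            if not _ATC_RE.match(c):
                raise ValueError(f"drug {d!r}: {c!r} is not a valid 7-char ATC code")
        norm[d] = cs
    n = len(ids)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            best = max(
                _atc_shared_levels(x, y)
                for x in norm[ids[i]]
                for y in norm[ids[j]]
            )
            values[i, j] = values[j, i] = best / 5.0
    return SimilarityMatrix(ids=ids, values=values)


def sparsify_similarity(
    S: SimilarityMatrix, threshold: float
) -> List[Tuple[str, str, float]]:
    """Off-diagonal pairs with similarity >= threshold, as weighted edges.

    Returns each unordered pair once, (a, b) with a < b, sorted.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    n = len(S.ids)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if S.values[i, j] >= threshold:
                a, b = sorted((S.ids[i], S.ids[j]))
                edges.append((a, b, float(S.values[i, j])))
    return sorted(edges)


def add_similarity_edges(
    net: HetNet,
    S: SimilarityMatrix,
    rel: RelationType,
    threshold: float = 0.5,
) -> int:
    """Threshold a similarity matrix into intra-type edges of ``net``.

    Returns the number of edges added. Ids absent from the network are added
    with the node type the relation demands.
    """
    if rel not in SIMILARITY_RELATIONS:
        raise ValueError(f"{rel} is not a similarity relation")
    t = RELATION_ENDPOINTS[rel][0]
    count = 0
    for a, b, w in sparsify_similarity(S, threshold):
        if a not in net:
            net.add_node(a, t)
        if b not in net:
            net.add_node(b, t)
        net.add_edge(a, b, rel, w)
        count += 1
    return count
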