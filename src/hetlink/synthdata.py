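"""Synthetic drug-gene-ADR networks with planted module structure.

The generator emulates the shape of a drug-gene interaction network enriched
with ADR causality: nodes of all three types are assigned round-robin to
latent modules; drug-gene and drug-ADR edges are Bernoulli draws with a high
within-module and low between-module probability (a stochastic block model on
the bipartite layers); and intra-type similarity scores concentrate near 1
for same-module pairs and near 0 otherwise, with truncated-Gaussian noise,
thresholded at 0.5 into similarity edges.

Every method in the pipeline — embedding proximity, Katz walk counts,
low-rank factorization — can in principle exploit the planted modules, which
makes the generator a common benchmark for comparing them.
"""

from __future__ import annotations

import json
import string
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

import numpy as np

from .hetnet import HetNet, NodeType, RelationType

__all__ = ["SynthConfig", "GroundTruth", "generate_hetnet", "generate_atc_codes"]


@dataclass(frozen=True)
class SynthConfig:
    """Planted-module network parameters.

    Defaults give the benchmark conditions used throughout the test-suite:
    4 modules over 60 drugs, 80 genes and 10 ADRs, dense within-module
    interactions (p_in=0.9) against sparse background (p_out=0.05).
    """

    n_drugs: int = 60
    n_genes: int = 80
    n_adrs: int = 10
    n_modules: int = 4
    p_in: float = 0.9
    p_out: float = 0.05
    p_adr_in: float = 0.9
    p_adr_out: float = 0.05
    sim_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_in", "p_out", "p_adr_in", "p_adr_out"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.sim_noise < 0:
            raise ValueError("sim_noise must be >= 0")
        if min(self.n_drugs, self.n_genes, self.n_adrs, self.n_modules) < 1:
            raise ValueError("all counts must be positive")
        if self.p_in < self.p_out:
            warnings.warn(
                "p_in < p_out: planted structure will not be learnable",
                stacklevel=2,
            )


@dataclass
class GroundTruth:
    """Module assignments and the latent drug-gene edge propensities."""

    modules: Dict[str, int]
    propensity: np.ndarray  # (n_drugs, n_genes) of p_in/p_out
    drug_ids: List[str]
    gene_ids: List[str]
    adr_ids: List[str]

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "modules": self.modules,
                    "drug_ids": self.drug_ids,
                    "gene_ids": self.gene_ids,
                    "adr_ids": self.adr_ids,
                },
                fh,
                indent=2,
            )


def _node_ids(prefix: str, n: int) -> List[str]:
    width = len(str(n - 1)) if n > 1 else 1
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def generate_hetnet(cfg: SynthConfig) -> Tuple[HetNet, GroundTruth]:
    """Draw a planted-module heterogeneous network; deterministic given seed."""
    rng = np.random.default_rng(cfg.seed)
    drugs = _node_ids("d", cfg.n_drugs)
    genes = _node_ids("g", cfg.n_genes)
    adrs = _node_ids("a", cfg.n_adrs)
    modules: Dict[str, int] = {}
    for ids in (drugs, genes, adrs):
        for i, nid in enumerate(ids):
            modules[nid] = i % cfg.n_modules

    net = HetNet()
    for d in drugs:
        net.add_node(d, NodeType.DRUG)
    for g in genes:
        net.add_node(g, NodeType.GENE)
    for a in adrs:
        net.add_node(a, NodeType.ADR)

    dmod = np.array([modules[d] for d in drugs])
    gmod = np.array([modules[g] for g in genes])
    amod = np.array([modules[a] for a in adrs])

    # drug-gene layer
    same_dg = dmod[:, None] == gmod[None, :]
    propensity = np.where(same_dg, cfg.p_in, cfg.p_out)
    draws = rng.random(propensity.shape)
    for i, d in enumerate(drugs):
        for j, g in enumerate(genes):
            if draws[i, j] < propensity[i, j]:
                net.add_edge(d, g, RelationType.DRUG_GENE, 1.0)

    # drug-ADR layer
    same_da = dmod[:, None] == amod[None, :]
    p_da = np.where(same_da, cfg.p_adr_in, cfg.p_adr_out)
    draws = rng.random(p_da.shape)
    for i, d in enumerate(drugs):
        for j, a in enumerate(adrs):
            if draws[i, j] < p_da[i, j]:
                net.add_edge(d, a, RelationType.DRUG_ADR, 1.0)

    # intra-type similarity layers, thresholded at 0.5
    def similarity_edges(ids: List[str], rel: RelationType) -> None:
        mods = np.array([modules[x] for x in ids])
        n = len(ids)
        eps = np.abs(rng.normal(0.0, cfg.sim_noise, size=(n, n)))
        for i in range(n):
            for j in range(i + 1, n):
                s = 1.0 - eps[i, j] if mods[i] == mods[j] else eps[i, j]
                s = float(np.clip(s, 0.0, 1.0))
                if s >= 0.5:
                    net.add_edge(ids[i], ids[j], rel, s)

    similarity_edges(drugs, RelationType.DRUG_DRUG_SIM)
    similarity_edges(genes, RelationType.GENE_GENE_SIM)

    truth = GroundTruth(
        modules=modules, propensity=propensity,
        drug_ids=drugs, gene_ids=genes, adr_ids=adrs,
    )
    return net, truth


#: alphabet per ATC level: (characters, length in the 7-char code)
_ATC_LEVEL_ALPHABETS = (
    (string.ascii_uppercase, 1),
    ([f"{i:02d}" for i in range(100)], 2),
    (string.ascii_uppercase, 1),
    (string.ascii_uppercase, 1),
    ([f"{i:02d}" for i in range(100)], 2),
)


def generate_atc_codes(
    truth: GroundTruth, levels_shared_within_module: int, seed: int = 0
) -> Dict[str, Set[str]]:
    """One valid 7-character ATC code per drug with controlled module sharing.

    Drugs of a module share the first ``levels_shared_within_module`` levels
    exactly.  The first unshared level cycles deterministically through its
    alphabet per drug within the module, so same-module similarity equals
    levels/5 exactly (while module sizes stay within that level's alphabet);
    level-1 letters are partitioned across modules, so with nothing shared the
    cross-module similarity is 0.
    """
    if not (0 <= levels_shared_within_module <= 5):
        raise ValueError("levels_shared_within_module must be in 0..5")
    rng = np.random.default_rng(seed)
    n_modules = max(truth.modules.values()) + 1
    letters = string.ascii_uppercase
    module_letters = {
        m: [letters[i] for i in range(m, len(letters), n_modules)]
        for m in range(n_modules)
    }
    # shared module prefix for the first `levels` levels
    module_prefix: Dict[int, List[str]] = {}
    for m in range(n_modules):
        parts = []
        for lvl, (alphabet, _width) in enumerate(_ATC_LEVEL_ALPHABETS):
            if lvl >= levels_shared_within_module:
                break
            if lvl == 0:
                parts.append(module_letters[m][0])
            else:
                parts.append(alphabet[int(rng.integers(len(alphabet)))])
        module_prefix[m] = parts

    codes: Dict[str, Set[str]] = {}
    within_counter: Dict[int, int] = {m: 0 for m in range(n_modules)}
    for d in truth.drug_ids:
        m = truth.modules[d]
        k = within_counter[m]
        within_counter[m] += 1
        parts = list(module_prefix[m])
        for lvl in range(levels_shared_within_module, 5):
            alphabet, _width = _ATC_LEVEL_ALPHABETS[lvl]
            if lvl == 0:
                # unshared level 1 still draws from the module's letter block
                alphabet = module_letters[m]
            if lvl == levels_shared_within_module:
                parts.append(alphabet[k % len(alphabet)])
            else:
                parts.append(alphabet[int(rng.integers(len(alphabet)))])
        codes[d] = {"".join(parts)}
    return codes
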