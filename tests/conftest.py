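import numpy as np
import pytest
from hypothesis import settings

import hetlink as hl

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def chain_net():
    """d1 - a1 - d2 - g1 - d3: a unique typed neighbor at every step of D-A-D-G-D."""
    net = hl.HetNet()
    net.add_node("d1", hl.NodeType.DRUG)
    net.add_node("d2", hl.NodeType.DRUG)
    net.add_node("d3", hl.NodeType.DRUG)
    net.add_node("a1", hl.NodeType.ADR)
    net.add_node("g1", hl.NodeType.GENE)
    net.add_edge("d1", "a1", hl.RelationType.DRUG_ADR)
    net.add_edge("d2", "a1", hl.RelationType.DRUG_ADR)
    net.add_edge("d2", "g1", hl.RelationType.DRUG_GENE)
    net.add_edge("d3", "g1", hl.RelationType.DRUG_GENE)
    return net


@pytest.fixture
def module_net():
    """Small planted-module network for mid-weight integration tests."""
    cfg = hl.SynthConfig(
        n_drugs=20, n_genes=24, n_adrs=6, n_modules=2, seed=7
    )
    net, truth = hl.generate_hetnet(cfg)
    return net, truth


@pytest.fixture(scope="session")
def benchmark_net():
    """The benchmark conditions: 60 drugs, 80 genes, 10 ADRs, 4 modules."""
    cfg = hl.SynthConfig(seed=0)
    net, truth = hl.generate_hetnet(cfg)
    return net, truth


@pytest.fixture(scope="session")
def benchmark_results(benchmark_net):
    """Held-out AUROCs of both embedding modes plus shuffled controls, 5 seeds.

    Session-scoped: the end-to-end benchmark is the most expensive computation
    in the suite and several tests consume different facets of it.
    """
    net, _truth = benchmark_net
    params_pp = hl.PipelineParams(
        num_walkers=10, walk_length=20, dimension=32, subspace_dim=8
    )
    params_v = hl.PipelineParams(
        num_walkers=10, walk_length=20, dimension=32, subspace_dim=8,
        mode="metapath2vec",
    )
    shuffle_rng = np.random.default_rng(2024)
    out = {"pp": [], "v": [], "control": []}
    for seed in range(5):
        train_net, pairs, labels = hl.make_split(net, hl.SplitSpec(seed=seed))
        s_pp = hl.run_pipeline(net, train_net, pairs, params_pp, seed=seed)
        s_v = hl.run_pipeline(net, train_net, pairs, params_v, seed=seed)
        shuffled = labels.copy()
        shuffle_rng.shuffle(shuffled)
        out["pp"].append(hl.auroc(s_pp, labels))
        out["v"].append(hl.auroc(s_v, labels))
        out["control"].append(hl.auroc(s_pp, shuffled))
    return out
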