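"""Edge-holdout evaluation: splits, ROC/AUROC, the end-to-end pipeline and
the one-parameter-at-a-time sweep harness.

A split removes a fraction of the drug-gene interaction edges from the
network; the removed edges are the test positives and an equal (or ratio-
scaled) number of never-observed drug-gene pairs are sampled as test
negatives.  Methods are trained on the reduced network only and scored on the
held-out pairs; AUROC is the tie-corrected rank statistic
P(score_pos > score_neg) + 0.5 P(score_pos = score_neg).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import sklearn.metrics

from . import baselines as bl
from .hetnet import HetNet, NodeType, RelationType
from .kbmf import (
    InteractionMatrix,
    KernelSet,
    kbmf_fit,
    kbmf_score,
    kernels_from_embeddings,
)
from .skipgram import NoiseModel, TrainConfig, train
from .walks import Metapath, WalkConfig, generate_walks, parse_metapath

__all__ = [
    "SplitSpec",
    "ROCResult",
    "PipelineParams",
    "make_split",
    "auroc",
    "roc_curve",
    "run_pipeline",
    "run_baseline",
    "parameter_sweep",
]


@dataclass(frozen=True)
class SplitSpec:
    holdout_fraction: float = 0.2
    negative_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.holdout_fraction < 1.0):
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.negative_ratio <= 0:
            raise ValueError("negative_ratio must be positive")


def make_split(
    net: HetNet, spec: SplitSpec
) -> Tuple[HetNet, List[Tuple[str, str]], np.ndarray]:
    """Hold out drug-gene edges and sample matched unobserved negatives.

    Returns (training network, test pairs, labels). The training network is a
    copy with the test-positive edges removed; isolated nodes stay.
    """
    positives = [(a, b) for a, b, _r, _w in net.edges(RelationType.DRUG_GENE)]
    if len(positives) < 5:
        raise ValueError("need at least 5 drug_gene edges to split")
    rng = np.random.default_rng(spec.seed)
    n_test = int(np.ceil(spec.holdout_fraction * len(positives)))
    test_idx = rng.choice(len(positives), size=n_test, replace=False)
    test_pos = [positives[i] for i in sorted(test_idx)]

    train_net = net.copy()
    for d, g in test_pos:
        train_net.remove_edge(d, g, RelationType.DRUG_GENE)

    drugs = net.nodes_of_type(NodeType.DRUG)
    genes = net.nodes_of_type(NodeType.GENE)
    observed = set(positives)
    n_neg = int(round(spec.negative_ratio * n_test))
    pool_size = len(drugs) * len(genes) - len(observed)
    if n_neg > pool_size:
        raise ValueError(
            f"cannot sample {n_neg} negatives from {pool_size} unobserved pairs"
        )
    negatives: List[Tuple[str, str]] = []
    seen = set()
    while len(negatives) < n_neg:
        i = int(rng.integers(len(drugs)))
        j = int(rng.integers(len(genes)))
        pair = (drugs[i], genes[j])
        if pair in observed or pair in seen:
            continue
        seen.add(pair)
        negatives.append(pair)

    pairs = test_pos + negatives
    labels = np.concatenate([np.ones(len(test_pos)), np.zeros(len(negatives))])
    return train_net, pairs, labels


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Tie-corrected rank-form AUROC, P(s+ > s-) + 0.5 P(s+ = s-)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined with a single class")
    return float(sklearn.metrics.roc_auc_score(labels, scores))


@dataclass
class ROCResult:
    """ROC points plus the trapezoidal area and class counts."""

    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float
    n_pos: int
    n_neg: int


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """Threshold-sweep ROC curve; its trapezoidal area equals the rank AUROC."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC undefined with a single class")
    fpr, tpr, _ = sklearn.metrics.roc_curve(labels, scores)
    area = float(np.trapezoid(tpr, fpr))
    return ROCResult(
        fpr=fpr, tpr=tpr, auroc=area,
        n_pos=int(labels.sum()), n_neg=int(len(labels) - labels.sum()),
    )


# ------------------------------------------------------------------ pipeline

@dataclass(frozen=True)
class PipelineParams:
    """End-to-end configuration: walks -> embedding -> kernels -> KBMF.

    Defaults for the walk/embedding parameters follow the base operating
    point w=1000, l=100, d=100; benchmark harnesses pass smaller values.
    """

    metapath: str = "Drug-ADR-Drug-Gene-Drug"
    num_walkers: int = 1000
    walk_length: int = 100
    dimension: int = 100
    window: int = 2
    negatives: int = 5
    epochs: int = 5
    learning_rate: float = 0.025
    mode: str = "metapath2vecpp"
    kernel_kind: str = "linear"
    subspace_dim: int = 8
    kbmf_iters: int = 30
    extra_drug_kernels: Tuple[np.ndarray, ...] = ()


def run_pipeline(
    net: HetNet,
    train_net: HetNet,
    test_pairs: Sequence[Tuple[str, str]],
    params: PipelineParams,
    seed: int = 0,
) -> np.ndarray:
    """Score held-out drug-gene pairs with metapath embedding + KBMF.

    Walks and the embedding are computed on the training network only; the
    interaction matrix masks out the test pairs.  Nodes that never enter a
    walk keep zero embedding vectors in the kernels.
    """
    mp = parse_metapath(params.metapath)
    corpus = generate_walks(
        train_net,
        mp,
        WalkConfig(
            num_walkers_per_start=params.num_walkers,
            walk_length=params.walk_length,
            seed=seed,
        ),
    )
    model = train(
        corpus,
        TrainConfig(
            dimension=params.dimension,
            window=params.window,
            negatives=params.negatives,
            epochs=params.epochs,
            learning_rate=params.learning_rate,
            seed=seed,
            mode=params.mode,
        ),
    )
    drug_ids = net.nodes_of_type(NodeType.DRUG)
    gene_ids = net.nodes_of_type(NodeType.GENE)
    Kd = kernels_from_embeddings(
        [model], "drug", kind=params.kernel_kind, ids=drug_ids, missing="zero"
    )
    if params.extra_drug_kernels:
        Kd = KernelSet(
            side="drug", ids=drug_ids,
            kernels=Kd.kernels + [np.asarray(K) for K in params.extra_drug_kernels],
        )
    Kg = kernels_from_embeddings(
        [model], "gene", kind=params.kernel_kind, ids=gene_ids, missing="zero"
    )
    Y = InteractionMatrix.from_hetnet(
        train_net, drug_ids, gene_ids, exclude_pairs=test_pairs
    )
    fitted = kbmf_fit(
        Kd, Kg, Y, X=params.subspace_dim, iters=params.kbmf_iters, seed=seed
    )
    return np.array(
        [kbmf_score(fitted, [d], [g])[0, 0] for d, g in test_pairs]
    )


def run_baseline(
    net: HetNet,
    train_net: HetNet,
    test_pairs: Sequence[Tuple[str, str]],
    method: str,
    seed: int = 0,
    katz_cfg: Optional[bl.KatzConfig] = None,
    walk_feature_length: int = 3,
    mf_rank: int = 8,
    mf_iters: int = 50,
) -> np.ndarray:
    """Score held-out pairs with one of the comparison methods."""
    if method == "katz":
        ids, S = bl.katz_scores(train_net, katz_cfg or bl.KatzConfig())
        index = {n: i for i, n in enumerate(ids)}
        return np.array([S[index[d], index[g]] for d, g in test_pairs])
    if method == "catapult":
        train_pos = [
            (a, b) for a, b, _r, _w in train_net.edges(RelationType.DRUG_GENE)
        ]
        drugs = train_net.nodes_of_type(NodeType.DRUG)
        genes = train_net.nodes_of_type(NodeType.GENE)
        known = set(train_pos) | set(test_pairs)
        unlabeled = [
            (d, g) for d in drugs for g in genes if (d, g) not in known
        ]
        all_pairs = sorted(set(train_pos) | set(unlabeled) | set(test_pairs))
        feats = bl.catapult_features(train_net, all_pairs, walk_feature_length)
        scorer = bl.catapult_train(feats, train_pos, unlabeled, seed=seed)
        return scorer.score(feats.rows(list(test_pairs)))
    if method == "mf":
        drug_ids = net.nodes_of_type(NodeType.DRUG)
        gene_ids = net.nodes_of_type(NodeType.GENE)
        Y = InteractionMatrix.from_hetnet(
            train_net, drug_ids, gene_ids, exclude_pairs=test_pairs
        )
        res = bl.mf_fit(Y, rank=mf_rank, iters=mf_iters, seed=seed)
        S = res.score_matrix()
        di = {d: i for i, d in enumerate(drug_ids)}
        gi = {g: i for i, g in enumerate(gene_ids)}
        return np.array([S[di[d], gi[g]] for d, g in test_pairs])
    raise ValueError(f"unknown baseline {method!r}")


def evaluate(
    net: HetNet,
    params: PipelineParams,
    split: SplitSpec,
) -> float:
    """One split, one pipeline run, one AUROC."""
    train_net, pairs, labels = make_split(net, split)
    scores = run_pipeline(net, train_net, pairs, params, seed=split.seed)
    return auroc(scores, labels)


_SWEEP_KEYS = {
    "num_walkers": "num_walkers",
    "w": "num_walkers",
    "walk_length": "walk_length",
    "l": "walk_length",
    "dimension": "dimension",
    "d": "dimension",
}


def parameter_sweep(
    net: HetNet,
    grid: Dict[str, Sequence],
    base: Optional[PipelineParams] = None,
    split: Optional[SplitSpec] = None,
    repeats: int = 5,
) -> pd.DataFrame:
    """Vary one walk/embedding parameter at a time from the base configuration.

    For every grid point the full pipeline runs once per repeat seed; the
    table reports mean and standard deviation of the held-out AUROC, mirroring
    a parameter/value/AUROC sensitivity layout.
    """
    base = base or PipelineParams()
    split = split or SplitSpec()
    rows = []
    for key, values in grid.items():
        field_name = _SWEEP_KEYS.get(key)
        if field_name is None:
            raise ValueError(
                f"unknown sweep parameter {key!r}; expected one of "
                f"{sorted(set(_SWEEP_KEYS))}"
            )
        for value in values:
            params = replace(base, **{field_name: int(value)})
            scores = [
                evaluate(net, params, replace(split, seed=split.seed + r))
                for r in range(repeats)
            ]
            rows.append(
                {
                    "parameter": field_name,
                    "value": int(value),
                    "auroc_mean": float(np.mean(scores)),
                    "auroc_std": float(np.std(scores)),
                    "repeats": repeats,
                }
            )
    return pd.DataFrame(rows)
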