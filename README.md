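# hetlink

Drug–gene interaction prediction on a heterogeneous drug–gene–ADR network:
metapath-constrained random walks, heterogeneous skip-gram embeddings
(metapath2vec and metapath2vec++), and kernelized Bayesian matrix
factorization (KBMF) scoring, with Katz, CATAPULT-style and plain
matrix-factorization baselines and ROC/AUROC evaluation.

## The problem

Knowing which human genes a drug perturbs matters both for drug efficacy and
for anticipating unwanted effects, but experimentally confirmed drug–gene
interactions are sparse. The network view treats the problem as link
prediction on a heterogeneous information network with three node types —
drugs, genes, and adverse drug reactions (ADRs) — joined by four relation
types: drug–drug similarity, gene–gene similarity, drug–gene interaction, and
drug–ADR causality. ADR causality edges act as an additional feature channel
for drugs: two drugs causing the same reactions are likely to touch related
genes.

## The method

1. **Metapath walks.** A random walker is constrained by a cyclic type scheme
   such as Drug–ADR–Drug–Gene–Drug: at step *i* it moves to a uniformly
   chosen neighbor whose type is the next one in the scheme. `w` walkers per
   drug, each up to `l` nodes long, produce a corpus of node sequences.
2. **Heterogeneous skip-gram.** Node embeddings `v_d` (input) and `v'_d`
   (output) maximize the average log probability of in-window contexts,
   `(1/N) Σ_n Σ_{-c≤j≤c, j≠0} log p(d_{n+j} | d_n)` with
   `p(g|d) = exp(v'_g·v_d) / Σ_x exp(v'_x·v_d)`, trained with negative
   sampling (`k` noise nodes per observed pair from a unigram^0.75
   distribution). metapath2vec draws negatives from the whole vocabulary;
   metapath2vec++ draws them only from the context node's type. Hierarchical
   softmax and noise-contrastive estimation are implemented as reference
   probability/loss computations.
3. **KBMF scoring.** Gram matrices of the embedding vectors serve as kernels
   `K_d^m`, `K_g^n` per side. Projections `A_d (N_d×X)`, `A_g (N_g×X)` and
   unconstrained Gaussian-prior kernel weights `e_d`, `e_g` form composite
   components `H_d = Σ_m e_d[m] A_d^T K_d^m` (likewise `H_g`); the score of a
   drug–gene pair is the bilinear product `(H_d^T H_g)_{ij}`. Inference is
   MAP alternating optimization of the penalized weighted squared error over
   the observed interaction matrix.
4. **Evaluation.** A fraction of drug–gene edges is held out, matched with
   uniformly sampled unobserved pairs, and methods are compared by
   tie-corrected AUROC.

## Worked example

```python
import numpy as np
import hetlink as hl

# planted-module benchmark network: 60 drugs, 80 genes, 10 ADRs, 4 modules
net, truth = hl.generate_hetnet(hl.SynthConfig(seed=0))

train_net, pairs, labels = hl.make_split(net, hl.SplitSpec(seed=0))
params = hl.PipelineParams(num_walkers=10, walk_length=20, dimension=32,
                           subspace_dim=8)
scores = hl.run_pipeline(net, train_net, pairs, params, seed=0)
print(f"metapath2vec++ AUROC: {hl.auroc(scores, labels):.4f}")
print(f"Katz AUROC:           "
      f"{hl.auroc(hl.run_baseline(net, train_net, pairs, 'katz', seed=0), labels):.4f}")
```

prints

```
metapath2vec++ AUROC: 0.9148
Katz AUROC:           0.9176
```

The embedding+KBMF pipeline recovers the planted module structure from the
held-out 20% of interaction edges (AUROC ≈ 0.91 versus 0.5 for chance). On
this synthetic benchmark the untyped Katz walk count is also strong — dense
within-module similarity cliques make raw path counts informative — and the
two trade places split by split; averaged over five splits the embedding
pipeline comes out ahead (see the reproduction script below), while the
CATAPULT-style learner and plain MF trail both.

The same pipeline is scriptable from the shell:

```bash
hetlink simulate --seed 0 --out data/
hetlink walk  --edges data/edges.tsv --metapath "Drug-ADR-Drug-Gene-Drug" \
              --walkers 10 --walk-length 20 --seed 0 --out data/corpus.txt
hetlink embed --corpus data/corpus.txt --edges data/edges.tsv \
              --dim 32 --mode metapath2vecpp --seed 0 --out data/emb.txt
hetlink eval  --edges data/edges.tsv --seed 0 --out data/auroc.tsv
```

## Layout

- `src/hetlink/hetnet.py` — typed network model, TSV edge-list I/O, ATC-code
  drug similarity, similarity-matrix thresholding
- `src/hetlink/walks.py` — metapath parsing and constrained walk generation
- `src/hetlink/skipgram.py` — softmax / hierarchical softmax / NCE /
  negative sampling, metapath2vec and metapath2vec++ training
- `src/hetlink/kbmf.py` — embedding kernels and kernelized Bayesian matrix
  factorization
- `src/hetlink/baselines.py` — Katz, CATAPULT-style PU learner, plain MF
- `src/hetlink/evaluation.py` — splits, ROC/AUROC, pipeline, parameter sweep
- `src/hetlink/synthdata.py` — planted-module synthetic network generator
- `src/hetlink/cli.py` — the `hetlink` command

See `docs/methods.md` for modeling assumptions, parameter defaults and known
limitations.
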