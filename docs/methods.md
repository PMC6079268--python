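# Methods

## Network model

The package represents a heterogeneous information network with node types
{drug, gene, adr} and four undirected relation types: `drug_drug_sim` and
`gene_gene_sim` (weights constrained to [0, 1]), `drug_gene` interaction and
`drug_adr` causality (nonnegative weights, 1.0 for plain presence). Edges are
undirected throughout; self-loops are rejected; duplicate edges collapse to
the maximum weight, so similarity evidence from multiple sources can never
sum above 1. All node/edge listings are returned in sorted order, which makes
every seeded downstream computation reproducible independent of insertion
order.

Drug similarity from WHO ATC codes uses the shared-leading-level fraction:
`sim(a, b) = max over code pairs of (consecutive shared leading levels) / 5`,
where the five levels occupy 1/2/1/1/2 characters of the 7-character code.
The score is monotone in hierarchy depth, bounded in [0, 1], and 1 exactly
for identical codes. Similarity matrices become network edges by
thresholding (default 0.5, off-diagonal entries at or above the threshold);
structural (fingerprint) similarity is accepted only as a precomputed matrix
and is never computed here. When both ATC and structural similarities are
available they are kept as separate inputs — the drug side of the KBMF model
can take each as an extra kernel rather than merging them into one relation.

## Metapath walks

A metapath is a cyclic sequence of node types (first = last), e.g.
Drug–ADR–Drug–Gene–Drug. Walks start at every node of the first type, `w`
walkers per start, each up to `l` nodes long; at position `i` the walker
moves to a neighbor of type `pattern(i+1)`, with the scheme repeated
cyclically when `l` exceeds its length. Transitions are uniform over the
typed neighbor set by default; weight-proportional transitions are an option
(similarity edges carry weights, but the default analysis does not use them
in the walk). A node with no neighbor of the required type truncates the
walk — truncation keeps every emitted walk a valid prefix of the type
pattern, rather than restarting or backtracking.

Because edges are undirected, the node a walker just left is always a
candidate for the return step of the pattern; walks can therefore oscillate
(d–a–d–…). This is inherent to uniform transitions on an undirected network
and is shared by standard metapath walkers.

Each (start node, walker) pair draws from its own random substream derived
from (seed, start index, walker index), so corpora are byte-identical across
runs and insensitive to generation order.

## Skip-gram training

The embedding keeps input vectors `v_d` and output vectors `v'_d`,
initialized uniformly in [−0.5/d, 0.5/d] from the seed. The window parameter
`c` is the symmetric context radius of the corpus objective. Training uses
negative sampling: for each observed (center, context) pair, `k` noise nodes
(default 5) are drawn from a unigram^0.75 distribution over the corpus
vocabulary, with the positive context excluded by redraw (at most 100 rounds,
then the pair is skipped with a log message). The unnormalized model score is
`p_θ = exp(v'·v)`, which makes the NCE true-label probability
`p_θ/(p_θ + k·q)` reduce to the logistic sigmoid when `k·q = 1` — the
standard SGNS reading. One gradient-ascent step updates only the center's
input vector and the sampled nodes' output vectors. The learning rate decays
linearly from 0.025 to 1e−4 of its initial value across all training windows.

metapath2vec draws negatives from the global noise distribution;
metapath2vec++ restricts them to the context node's type using per-type
renormalized distributions. Both modes draw per context row from a
cumulative-probability table, so on a single-type network — where the
per-type table equals the global table — the two modes are bit-identical.

Hierarchical softmax is implemented as a probability computation over a
Huffman tree built from vocabulary frequencies (left branch = bit 1, with
`P(left) = σ(w_internal · v_center)`); the default trainer uses negative
sampling, as the metapath2vec family does. Training is single-threaded and
bit-deterministic given the seed; that determinism is part of the contract,
and any parallel variant would forfeit it.

## KBMF

Each side carries one kernel per embedding (Gram matrix `E Eᵀ` of the side's
input vectors, or its cosine variant), jittered by 1e−8 on the diagonal to
stay numerically PSD; the drug side can take additional similarity-matrix
kernels. The model projects mixed kernels into an `X`-dimensional subspace:
`H_d = Σ_m e_d[m] A_dᵀ K_d^m`, `H_g = Σ_n e_g[n] A_gᵀ K_g^n`, and scores
pairs bilinearly as `H_dᵀ H_g`. Kernel weights are unconstrained reals under
a Gaussian prior.

Inference is MAP alternating optimization rather than full variational
Bayes: the scoring rule (the posterior-mean structure `H_dᵀH_g`) is
identical, while the implementation is drastically simpler, deterministic
and directly testable. Each block (`A_d`, `e_d`, `A_g`, `e_g`) is set to the
exact minimizer of

    L = Σ_ij W_ij (Y_ij − S_ij)² + λ (‖A_d‖² + ‖A_g‖² + ‖e_d‖² + ‖e_g‖²)

given the others (projection blocks via a ridge least-squares in vec(A),
weight blocks via a small ridge solve), so the objective trace is
non-increasing by construction and is checked to 1e−9 in the tests. Prior
terms enter only for parameters actually optimized; with weights fixed at 1
and single identity kernels the model reduces exactly to plain masked matrix
factorization, which the test suite verifies against the independent
row-wise-ALS implementation in the baselines module.

Only masked (training) entries enter the loss; held-out test pairs are
excluded from the mask entirely. Zero entries inside the mask are unknowns,
not confirmed negatives, and are down-weighted by a factor 0.1 — a
positive-unlabeled asymmetry. Defaults: `X = 20` (the pipeline harness uses
`X = 8` at benchmark scale), prior and noise precision 1.0.

## Baselines

- **Katz**: `S = Σ_{ℓ=1..K} β^ℓ A^ℓ` on the binary, untyped adjacency over
  all nodes (the method is defined on an unweighted network, which is also
  its known weakness here); truncated series with defaults `K = 4`,
  `β = 0.01`.
- **CATAPULT-style**: per drug–gene pair, the counts of heterogeneous walks
  of lengths 1..L (sparse matrix powers), a PU step that samples provisional
  negatives uniformly from the unlabeled pairs, and an L2-regularized
  logistic scorer with positives up-weighted by the sampling ratio. This is
  the method's core recipe — walk-count features, PU negative sampling,
  biased linear classifier — not the original gene–phenotype feature set.
- **Plain MF**: mask-aware alternating ridge least squares on the
  interaction matrix; also serves as the no-kernel KBMF comparator, with
  interaction-profile information only.

## Evaluation protocol

`make_split` removes `⌈0.2 × |drug_gene edges|⌉` randomly chosen interaction
edges; test positives are the removed edges and test negatives are an equal
number (ratio 1) of uniformly sampled never-observed drug–gene pairs. The
protocol is repeated over 5 seeds and reported as mean ± std. Nodes isolated
by edge removal stay in the network; genes that consequently never enter a
walk receive zero embedding vectors in the kernels and are scored anyway
(their scores are uninformative, which is the honest price of the holdout).

AUROC is the tie-corrected rank statistic
`P(s⁺ > s⁻) + ½ P(s⁺ = s⁻)`; the threshold-sweep ROC curve's trapezoidal
area must agree with it to 1e−12, and both are checked against an explicit
O(n²) pair-counting oracle in the tests.

The sweep harness varies one parameter at a time (number of walkers `w`,
walk length `l`, embedding dimension `d`) from a base configuration. The
base operating point defaults to `w = 1000`, `l = 100`, `d = 100`; the
synthetic benchmark uses `w = 10`, `l = 20`, `d = 32`, which this generator's
network sizes saturate — larger values only add runtime.

## Synthetic data

The generator emulates a drug–gene interaction network with latent module
structure: nodes assigned round-robin to `n_modules` modules; drug–gene and
drug–ADR edges Bernoulli with `p_in` within modules (default 0.9) and
`p_out` between (default 0.05); intra-type similarity
`1[same module]·(1−|ε|) + 1[different]·|ε|` with `ε ~ N(0, sim_noise)`,
clipped to [0, 1] and thresholded at 0.5 into edges. Defaults (60 drugs, 80
genes, 10 ADRs, 4 modules) give a network every method in the comparison can
in principle exploit — embedding proximity, path counts and low-rank
structure all align with the planted modules — which is exactly what makes
it a fair common benchmark.

What it does **not** emulate: the scale and degree heterogeneity of real
drug–gene resources, expression-signature-derived edge weights, ontology
structure over ADRs, or correlated noise between similarity sources. Passing
the benchmark demonstrates that each implementation exploits planted
block structure end-to-end and that the components compose correctly; it
does not certify performance on real pharmacological data.

Synthetic ATC codes share the first `levels` levels within a module; the
first unshared level cycles deterministically through its alphabet per drug
so the within-module similarity equals `levels/5` exactly (valid while a
module has no more drugs than that level's alphabet size), and level-1
letters are partitioned across modules so fully unshared codes score 0
across modules.

## Numerical choices and degenerate inputs

- Softmax probabilities are computed with max-subtraction for stability.
- A vocabulary of size 1 cannot be trained with negative sampling and is
  rejected; a corpus with no start-type nodes yields an empty corpus with a
  warning rather than an error.
- Huffman ties are broken by sorted vocabulary order (deterministic trees).
- Kernel PSD is enforced up to −1e−8 on the smallest eigenvalue; similarity
  matrices promoted to kernels are shifted onto the PSD cone when needed.
- `X` may not exceed min(N_d, N_g); an empty observation mask is an error.
- Benchmark problem sizes (60×80 network, walks 10×20, d=32, X=8, 5 seeds)
  were chosen so the complete evaluation runs in minutes on a single core
  while leaving the planted structure clearly learnable.

## Known limitations

- MAP point estimates replace the variational posterior of classical KBMF;
  no predictive uncertainty is produced.
- The projection update solves a (N·X)-dimensional ridge system per side and
  iteration, which is exact but scales poorly past a few thousand nodes per
  side.
- Embeddings for nodes isolated in a training split are zero vectors, and
  their pair scores carry no signal.
- The walker's uniform transition ignores edge weights by default; the
  weighted option is provided but untuned.
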