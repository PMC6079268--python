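"""Skip-gram machinery: softmax variants, NCE, negative sampling, training."""

import math

import numpy as np
import pytest

import hetlink as hl
from hetlink.skipgram import (
    EmbeddingModel,
    NoiseModel,
    build_huffman_tree,
    nce_instance_loss_and_grad,
    nce_true_prob,
    sgns_instance_loss_and_grad,
    softmax_all,
)
from hetlink.walks import WalkCorpus


def _model(ids, in_vecs, out_vecs, types=None):
    types = types or {i: hl.NodeType.DRUG for i in ids}
    return EmbeddingModel(
        ids=ids, types=types,
        in_vecs=np.asarray(in_vecs, float), out_vecs=np.asarray(out_vecs, float),
    )


def _random_model(n, d, seed, types=None):
    rng = np.random.default_rng(seed)
    ids = [f"n{i}" for i in range(n)]
    return _model(ids, rng.normal(size=(n, d)), rng.normal(size=(n, d)), types)


def _corpus(walks, types=None):
    freq = {}
    for w in walks:
        for t in w:
            freq[t] = freq.get(t, 0) + 1
    types = types or {}
    vocab = {
        t: (types.get(t, hl.NodeType.DRUG), f) for t, f in sorted(freq.items())
    }
    return WalkCorpus(walks=walks, vocabulary=vocab)


class TestSoftmax:
    def test_zero_output_vectors_give_uniform(self):
        m = _model(["a", "b", "c", "d"], np.ones((4, 3)), np.zeros((4, 3)))
        for ctx in m.ids:
            assert hl.softmax_prob("a", ctx, m) == pytest.approx(0.25)

    def test_two_node_logits_zero_and_ln3(self):
        # inner products {0, ln 3} -> probabilities {0.25, 0.75}
        in_vecs = [[1.0], [0.0]]
        out_vecs = [[0.0], [math.log(3.0)]]
        m = _model(["a", "b"], in_vecs, out_vecs)
        assert hl.softmax_prob("a", "a", m) == pytest.approx(0.25)
        assert hl.softmax_prob("a", "b", m) == pytest.approx(0.75)

    def test_distribution_sums_to_one(self):
        m = _random_model(12, 5, seed=0)
        total = sum(hl.softmax_prob("n3", ctx, m) for ctx in m.ids)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_unknown_node_raises(self):
        m = _random_model(3, 2, seed=1)
        with pytest.raises(KeyError):
            hl.softmax_prob("zz", "n0", m)


class TestSkipgramObjective:
    def test_single_node_vocabulary_objective_is_zero(self):
        m = _model(["a"], [[0.3, 0.1]], [[0.2, -0.1]])
        corpus = _corpus([["a", "a", "a"]])
        assert hl.skipgram_objective(corpus, m, c=2) == pytest.approx(0.0)

    def test_matches_brute_force_window_sum(self):
        m = _random_model(5, 4, seed=2)
        walk = ["n0", "n3", "n1", "n4", "n2"]
        corpus = _corpus([walk])
        c = 2
        # independent oracle: direct double loop with explicit softmax
        total = 0.0
        for n, center in enumerate(walk):
            logits = m.out_vecs @ m.in_vecs[m.index[center]]
            probs = np.exp(logits) / np.exp(logits).sum()
            for j in range(len(walk)):
                if j != n and abs(j - n) <= c:
                    total += math.log(probs[m.index[walk[j]]])
        expected = total / len(walk)
        assert hl.skipgram_objective(corpus, m, c) == pytest.approx(expected, rel=1e-12)

    def test_objective_nonpositive(self):
        m = _random_model(6, 3, seed=3)
        corpus = _corpus([["n0", "n1", "n2", "n3"]])
        assert hl.skipgram_objective(corpus, m, c=2) <= 0.0

    def test_raising_observed_pair_logit_increases_objective(self):
        m = _random_model(4, 3, seed=4)
        corpus = _corpus([["n0", "n1"]])
        before = hl.skipgram_objective(corpus, m, c=1)
        m.out_vecs[m.index["n1"]] += 0.5 * m.in_vecs[m.index["n0"]]
        m.out_vecs[m.index["n0"]] += 0.5 * m.in_vecs[m.index["n1"]]
        assert hl.skipgram_objective(corpus, m, c=1) > before

    def test_empty_corpus_rejected(self):
        m = _random_model(3, 2, seed=5)
        with pytest.raises(ValueError):
            hl.skipgram_objective(_corpus([]), m, c=1)


class TestHierarchicalSoftmax:
    def test_two_leaves_complementary(self):
        m = _random_model(2, 3, seed=6)
        tree = build_huffman_tree({"n0": 5, "n1": 3}, dimension=3, seed=1)
        p0 = hl.hierarchical_softmax_prob("n0", "n0", tree, m)
        p1 = hl.hierarchical_softmax_prob("n0", "n1", tree, m)
        assert p0 + p1 == pytest.approx(1.0)

    def test_balanced_tree_zero_vectors_uniform(self):
        m = _random_model(4, 3, seed=7)
        tree = build_huffman_tree({f"n{i}": 1 for i in range(4)}, dimension=3)
        for leaf in m.ids:
            assert hl.hierarchical_softmax_prob("n0", leaf, tree, m) == \
                pytest.approx(0.25)

    def test_leaf_probabilities_sum_to_one(self):
        m = _random_model(8, 4, seed=8)
        freqs = {f"n{i}": i + 1 for i in range(8)}
        tree = build_huffman_tree(freqs, dimension=4, seed=2)
        total = sum(
            hl.hierarchical_softmax_prob("n2", leaf, tree, m) for leaf in m.ids
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_prefix_free_codes_and_internal_count(self):
        freqs = {f"n{i}": 2 ** i for i in range(6)}
        tree = build_huffman_tree(freqs, dimension=2)
        assert tree.num_internal == 5
        codes = list(tree.codes.values())
        for i, a in enumerate(codes):
            for b in codes[i + 1:]:
                shorter, longer = sorted((a, b), key=len)
                assert longer[: len(shorter)] != shorter

    def test_absent_node_raises(self):
        m = _random_model(3, 2, seed=9)
        tree = build_huffman_tree({"n0": 1, "n1": 1}, dimension=2)
        with pytest.raises(KeyError):
            hl.hierarchical_softmax_prob("n0", "n2", tree, m)


def _uniform_noise(model):
    n = model.vocab_size
    return NoiseModel(
        distribution={i: 1.0 / n for i in model.ids},
        types=model.types,
    )


class TestNce:
    def test_true_prob_half_when_ptheta_equals_kq(self):
        # p_theta = k*q(d) makes the discriminator indifferent
        m = _model(["a", "b"], [[0.0], [0.0]], [[0.0], [0.0]])  # p_theta = 1
        noise = NoiseModel(
            distribution={"a": 0.5, "b": 0.5}, types={x: hl.NodeType.DRUG for x in "ab"}
        )
        assert nce_true_prob(m, noise, k=2, center="a", candidate="b") == \
            pytest.approx(0.5)

    def test_true_and_noise_probs_sum_to_one(self):
        m = _random_model(4, 3, seed=10)
        noise = _uniform_noise(m)
        k = 3
        p1 = nce_true_prob(m, noise, k, "n0", "n2")
        # complement from the shared denominator
        ptheta = math.exp(m.out_vecs[2] @ m.in_vecs[0])
        p0 = (k * 0.25) / (ptheta + k * 0.25)
        assert p1 + p0 == pytest.approx(1.0)

    def test_three_node_toy_matches_hand_evaluation(self):
        in_vecs = [[0.5, 0.0], [0.0, 0.5], [0.5, 0.5]]
        out_vecs = [[0.2, 0.1], [-0.1, 0.3], [0.4, -0.2]]
        m = _model(["x", "y", "z"], in_vecs, out_vecs)
        noise = _uniform_noise(m)
        k = 2
        insts = [
            hl.TrainingInstance("x", frozenset({"y"}), "y", 1),
            hl.TrainingInstance("x", frozenset({"y"}), "z", 0),
            hl.TrainingInstance("x", frozenset({"y"}), "y", 1),
        ]
        # hand evaluation with explicit numbers
        q = 1.0 / 3.0
        p_y = math.exp(-0.1 * 0.5 + 0.3 * 0.0)
        p_z = math.exp(0.4 * 0.5 - 0.2 * 0.0)
        term_pos = math.log(p_y / (p_y + k * q))
        term_neg = math.log(k * q / (p_z + k * q))
        expected = (2 * term_pos + term_neg) / 2  # two positive observations
        assert hl.nce_loss(insts, m, noise, k) == pytest.approx(expected, rel=1e-12)

    def test_label_must_match_membership(self):
        with pytest.raises(ValueError):
            hl.TrainingInstance("x", frozenset({"y"}), "y", 0)


class TestNegativeSampling:
    def test_sigmoid_half_at_zero_inner_product(self):
        m = _model(["a", "b"], [[0.0, 0.0], [1.0, 1.0]], [[0.0, 0.0], [0.0, 0.0]])
        loss, _, _ = sgns_instance_loss_and_grad(m, "a", "b", [])
        assert math.exp(loss) == pytest.approx(0.5)

    def test_positive_and_negative_probs_complementary(self):
        m = _random_model(3, 4, seed=11)
        s = float(m.out_vecs[1] @ m.in_vecs[0])
        p1 = 1.0 / (1.0 + math.exp(-s))
        p0 = 1.0 / (1.0 + math.exp(s))
        assert p1 + p0 == pytest.approx(1.0)

    @pytest.mark.parametrize("loss_kind", ["sgns", "nce"])
    def test_analytic_gradient_matches_central_difference(self, loss_kind):
        m = _random_model(5, 3, seed=12)
        noise = _uniform_noise(m)
        center, positive, negatives = "n0", "n2", ["n1", "n3", "n4"]
        k = len(negatives)

        def loss_fn(model):
            if loss_kind == "sgns":
                return sgns_instance_loss_and_grad(model, center, positive, negatives)[0]
            return nce_instance_loss_and_grad(model, noise, k, center, positive, negatives)[0]

        if loss_kind == "sgns":
            _, grad_in, grad_out = sgns_instance_loss_and_grad(
                m, center, positive, negatives
            )
        else:
            _, grad_in, grad_out = nce_instance_loss_and_grad(
                m, noise, k, center, positive, negatives
            )

        eps = 1e-6
        for d in range(3):
            m2 = _model(list(m.ids), m.in_vecs.copy(), m.out_vecs.copy())
            m2.in_vecs[0, d] += eps
            m3 = _model(list(m.ids), m.in_vecs.copy(), m.out_vecs.copy())
            m3.in_vecs[0, d] -= eps
            num = (loss_fn(m2) - loss_fn(m3)) / (2 * eps)
            assert abs(num - grad_in[d]) / max(abs(num), 1e-8) < 1e-5
        for node, g in grad_out.items():
            i = m.index[node]
            for d in range(3):
                m2 = _model(list(m.ids), m.in_vecs.copy(), m.out_vecs.copy())
                m2.out_vecs[i, d] += eps
                m3 = _model(list(m.ids), m.in_vecs.copy(), m.out_vecs.copy())
                m3.out_vecs[i, d] -= eps
                num = (loss_fn(m2) - loss_fn(m3)) / (2 * eps)
                assert abs(num - g[d]) / max(abs(num), 1e-8) < 1e-5

    def test_update_touches_only_center_and_sampled_rows(self):
        m = _random_model(6, 3, seed=13)
        before_in, before_out = m.in_vecs.copy(), m.out_vecs.copy()
        noise = _uniform_noise(m)
        inst = hl.TrainingInstance("n0", frozenset({"n1"}), "n1", 1)
        rng = np.random.default_rng(0)
        hl.negative_sampling_update(inst, m, noise, k=2, lr=0.1, rng=rng)
        changed_in = [i for i in range(6) if not np.array_equal(m.in_vecs[i], before_in[i])]
        assert changed_in == [0]  # only the center's input vector
        changed_out = {
            m.ids[i] for i in range(6)
            if not np.array_equal(m.out_vecs[i], before_out[i])
        }
        assert "n1" in changed_out  # the positive context's output vector
        assert len(changed_out) <= 1 + 2  # positive + at most k sampled negatives

    def test_nonpositive_learning_rate_rejected(self):
        m = _random_model(3, 2, seed=14)
        noise = _uniform_noise(m)
        inst = hl.TrainingInstance("n0", frozenset({"n1"}), "n1", 1)
        with pytest.raises(ValueError):
            hl.negative_sampling_update(
                inst, m, noise, k=1, lr=0.0, rng=np.random.default_rng(0)
            )


class TestHeterogeneousObjective:
    def test_no_edges_gives_zero(self):
        net = hl.HetNet()
        net.add_node("d1", hl.NodeType.DRUG)
        net.add_node("g1", hl.NodeType.GENE)
        m = _model(
            ["d1", "g1"], np.ones((2, 2)), np.ones((2, 2)),
            types={"d1": hl.NodeType.DRUG, "g1": hl.NodeType.GENE},
        )
        assert hl.heterogeneous_objective(net, m) == 0.0

    def test_matches_brute_force_triple_loop(self, chain_net):
        rng = np.random.default_rng(15)
        ids = chain_net.node_ids()
        m = _model(
            ids, rng.normal(size=(len(ids), 3)), rng.normal(size=(len(ids), 3)),
            types=dict(chain_net.nodes),
        )
        expected = 0.0
        for d in ids:
            for t in hl.NodeType:
                for g, _w in chain_net.typed_neighbors(d, t):
                    logits = m.out_vecs @ m.in_vecs[m.index[d]]
                    probs = np.exp(logits) / np.exp(logits).sum()
                    expected += math.log(probs[m.index[g]])
        assert hl.heterogeneous_objective(chain_net, m) == \
            pytest.approx(expected, rel=1e-12)

    def test_adding_edge_adds_two_nonpositive_terms(self, chain_net):
        rng = np.random.default_rng(16)
        ids = chain_net.node_ids()
        m = _model(
            ids, rng.normal(size=(len(ids), 3)), rng.normal(size=(len(ids), 3)),
            types=dict(chain_net.nodes),
        )
        before = hl.heterogeneous_objective(chain_net, m)
        chain_net.add_edge("d1", "g1", hl.RelationType.DRUG_GENE)
        after = hl.heterogeneous_objective(chain_net, m)
        p1 = hl.softmax_prob("d1", "g1", m)
        p2 = hl.softmax_prob("g1", "d1", m)
        assert after - before == pytest.approx(math.log(p1) + math.log(p2))
        assert after < before  # both terms are negative


class TestNoiseModel:
    def test_global_and_per_type_distributions_normalized(self, module_net):
        net, _ = module_net
        corpus = hl.generate_walks(
            net, hl.parse_metapath("Drug-ADR-Drug-Gene-Drug"),
            hl.WalkConfig(num_walkers_per_start=3, walk_length=10, seed=0),
        )
        noise = NoiseModel.from_corpus(corpus)
        assert sum(noise.distribution.values()) == pytest.approx(1.0, abs=1e-9)
        support = set()
        for t, sub in noise.per_type.items():
            assert sum(sub.values()) == pytest.approx(1.0, abs=1e-9)
            assert not (support & set(sub))
            support |= set(sub)
        assert support == set(noise.distribution)


class TestTrain:
    def test_zero_epochs_returns_seeded_initialization(self):
        corpus = _corpus([["a", "b", "a", "b"]])
        cfg = hl.TrainConfig(dimension=4, epochs=0, seed=9)
        model = hl.train(corpus, cfg)
        expected = EmbeddingModel.init_random(corpus.vocabulary, 4, seed=9)
        np.testing.assert_array_equal(model.in_vecs, expected.in_vecs)
        np.testing.assert_array_equal(model.out_vecs, expected.out_vecs)
        assert np.abs(model.in_vecs).max() <= 0.5 / 4

    def test_degenerate_vocabulary_rejected(self):
        corpus = _corpus([["a", "a", "a"]])
        with pytest.raises(ValueError, match="degenerate"):
            hl.train(corpus, hl.TrainConfig(dimension=2, epochs=1, seed=0))

    def test_pp_mode_negatives_match_context_type(self, module_net):
        net, _ = module_net
        corpus = hl.generate_walks(
            net, hl.parse_metapath("Drug-ADR-Drug-Gene-Drug"),
            hl.WalkConfig(num_walkers_per_start=1, walk_length=8, seed=0),
        )
        types = {n: net.nodes[n] for n in corpus.vocabulary}
        seen = []

        def record(center, context, negatives):
            seen.append((types[context], {types[n] for n in negatives}))

        hl.train(
            corpus,
            hl.TrainConfig(dimension=8, epochs=1, seed=0, mode="metapath2vecpp"),
            negative_callback=record,
        )
        assert seen
        for ctx_type, neg_types in seen:
            assert neg_types == {ctx_type}

    def test_training_improves_full_softmax_objective(self, module_net):
        net, _ = module_net
        corpus = hl.generate_walks(
            net, hl.parse_metapath("Drug-ADR-Drug-Gene-Drug"),
            hl.WalkConfig(num_walkers_per_start=3, walk_length=12, seed=1),
        )
        cfg0 = hl.TrainConfig(dimension=16, epochs=0, seed=1)
        cfg = hl.TrainConfig(dimension=16, epochs=10, seed=1)
        before = hl.skipgram_objective(corpus, hl.train(corpus, cfg0), c=2)
        after = hl.skipgram_objective(corpus, hl.train(corpus, cfg), c=2)
        assert after > before

    def test_disconnected_communities_separate_in_embedding(self):
        cfg = hl.SynthConfig(
            n_drugs=16, n_genes=20, n_adrs=6, n_modules=2,
            p_out=0.0, p_adr_out=0.0, sim_noise=0.0, seed=3,
        )
        net, truth = hl.generate_hetnet(cfg)
        corpus = hl.generate_walks(
            net, hl.parse_metapath("Drug-ADR-Drug-Gene-Drug"),
            hl.WalkConfig(num_walkers_per_start=10, walk_length=20, seed=3),
        )
        model = hl.train(corpus, hl.TrainConfig(dimension=16, epochs=10, seed=3))
        drugs = [d for d in truth.drug_ids if d in model.index]
        vecs = {d: model.input_vector(d) for d in drugs}

        def cos(a, b):
            return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))

        intra, inter = [], []
        for i, a in enumerate(drugs):
            for b in drugs[i + 1:]:
                sim = cos(vecs[a], vecs[b])
                (intra if truth.modules[a] == truth.modules[b] else inter).append(sim)
        assert np.mean(intra) > np.mean(inter)

    def test_modes_identical_on_single_type_network(self):
        net = hl.HetNet()
        for i in range(8):
            net.add_node(f"d{i}", hl.NodeType.DRUG)
        rng = np.random.default_rng(0)
        for i in range(8):
            for j in range(i + 1, 8):
                if rng.random() < 0.5:
                    net.add_edge(f"d{i}", f"d{j}", hl.RelationType.DRUG_DRUG_SIM, 0.9)
        corpus = hl.generate_walks(
            net, hl.parse_metapath("Drug-Drug"),
            hl.WalkConfig(num_walkers_per_start=4, walk_length=10, seed=2),
        )
        m1 = hl.train(corpus, hl.TrainConfig(dimension=8, epochs=2, seed=5,
                                             mode="metapath2vec"))
        m2 = hl.train(corpus, hl.TrainConfig(dimension=8, epochs=2, seed=5,
                                             mode="metapath2vecpp"))
        np.testing.assert_array_equal(m1.in_vecs, m2.in_vecs)
        np.testing.assert_array_equal(m1.out_vecs, m2.out_vecs)


class TestEmbeddingIO:
    def test_word2vec_text_round_trip(self, tmp_path):
        m = _random_model(5, 3, seed=17)
        path = tmp_path / "emb.txt"
        m.save(path, types_path=tmp_path / "emb.types.tsv")
        header = path.read_text().splitlines()[0]
        assert header == "5 3"
        loaded = EmbeddingModel.load(path, tmp_path / "emb.types.tsv")
        assert loaded.ids == m.ids
        np.testing.assert_allclose(loaded.in_vecs, m.in_vecs)
        assert loaded.types == m.types
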