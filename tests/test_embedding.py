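"""Pair-similarity embedding: scoring identities, PLR, and optimization."""

import numpy as np
import pytest

from kprfunc import embedding
from kprfunc.alphabet import ALPHABET, N_PAIRS, blosum62, pair_feature_index
from kprfunc.embedding import (
    OptimizeConfig,
    ScoringModel,
    average_similarity,
    embed,
    embed_dataset,
    fit_plr,
    load_scoring_model,
    optimize_embedding,
    save_scoring_model,
)

RNG = np.random.default_rng(2024)


def random_peptide(length=61, rng=RNG):
    return "".join(rng.choice(list(ALPHABET), size=length))


def brute_force_similarity(peptide, positives, W, M):
    """Direct double-loop evaluation of the average-similarity formula."""
    total = 0.0
    for j, pj in enumerate(peptide):
        inner = sum(M[ALPHABET.index(pj), ALPHABET.index(k[j])] for k in positives)
        total += inner * W[j]
    return total / len(positives)


class TestAverageSimilarity:
    def test_self_similarity_of_poly_alanine(self):
        model = ScoringModel(positives=["A" * 61])
        # 61 positions, each scoring BLOSUM62[A, A] = 4 at weight 1
        assert average_similarity("A" * 61, model) == pytest.approx(61 * 4)

    def test_zero_weights_annihilate(self):
        model = ScoringModel(positives=[random_peptide()], weights=np.zeros(61))
        assert average_similarity(random_peptide(), model) == 0.0

    def test_matches_double_loop_oracle(self):
        positives = [random_peptide() for _ in range(2)]
        W = RNG.uniform(0, 2, size=61)
        model = ScoringModel(positives=positives, weights=W)
        for _ in range(3):
            p = random_peptide()
            expected = brute_force_similarity(p, positives, W, model.matrix)
            assert average_similarity(p, model) == pytest.approx(expected, abs=1e-9)

    def test_character_outside_alphabet_named(self):
        model = ScoringModel(positives=["A" * 61])
        with pytest.raises(ValueError, match="'J' at peptide position 3"):
            average_similarity("AA" + "J" + "A" * 58, model)


class TestEmbed:
    def test_vector_has_300_features(self):
        model = ScoringModel(positives=[random_peptide()])
        assert embed(random_peptide(), model).shape == (300,)
        assert N_PAIRS == 300

    def test_zero_weights_give_zero_vector(self):
        model = ScoringModel(positives=[random_peptide()], weights=np.zeros(61))
        assert not embed(random_peptide(), model).any()

    def test_sum_identity_with_average_similarity(self):
        positives = [random_peptide() for _ in range(7)]
        model = ScoringModel(positives=positives, weights=RNG.uniform(0, 2, 61))
        for _ in range(10):
            p = random_peptide()
            v = embed(p, model)
            assert v.sum() == pytest.approx(average_similarity(p, model), abs=1e-9)

    def test_linear_in_position_weights(self):
        positives = [random_peptide() for _ in range(3)]
        W = RNG.uniform(0, 2, 61)
        p = random_peptide()
        v1 = embed(p, ScoringModel(positives=positives, weights=W))
        v3 = embed(p, ScoringModel(positives=positives, weights=3.0 * W))
        np.testing.assert_allclose(v3, 3.0 * v1, rtol=1e-12)

    def test_canonical_pair_order_is_data_independent(self):
        assert pair_feature_index("A", "A") == 0
        assert pair_feature_index("A", "C") == 1
        assert pair_feature_index("C", "A") == 1
        assert pair_feature_index("*", "*") == 299

    def test_leave_self_out_excludes_own_contribution(self):
        peps = [random_peptide() for _ in range(4)]
        model = ScoringModel(positives=peps)
        reduced = ScoringModel(positives=peps[1:])
        with_lso = embed_dataset([peps[0]], model, leave_self_out=True)[0]
        # equals embedding against the other positives only
        expected = embed(peps[0], reduced)
        np.testing.assert_allclose(with_lso, expected, rtol=1e-12)


class TestFitPlr:
    def _signal_data(self, n=200, separation=4.0, seed=0):
        rng = np.random.default_rng(seed)
        y = np.arange(n) % 2
        X = rng.normal(size=(n, 10))
        X[:, 0] += separation * y
        return X, y

    def test_separable_data_reaches_high_cv_auc(self):
        X, y = self._signal_data(separation=8.0)
        assert fit_plr(X, y, seed=0).cv_auc >= 0.99

    def test_shuffled_labels_score_near_chance(self):
        X, y = self._signal_data(separation=8.0)
        rng = np.random.default_rng(42)
        assert 0.4 <= fit_plr(X, rng.permutation(y), seed=0).cv_auc <= 0.6

    def test_deterministic_given_seed(self):
        X, y = self._signal_data()
        assert fit_plr(X, y, seed=3).cv_auc == fit_plr(X, y, seed=3).cv_auc

    def test_single_class_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError, match="both classes"):
            fit_plr(X, np.zeros(10, dtype=int))


def _motif_dataset(n_per_class=30, seed=5):
    """Positives carry G at window offset +2 (index 32)."""
    rng = np.random.default_rng(seed)
    aa = list("ACDEFGHILMNPQRSTVWY")
    peps, labels = [], []
    for lab in (1, 0):
        for _ in range(n_per_class):
            chars = list(rng.choice(aa, size=61))
            chars[30] = "K"
            if lab and rng.random() < 0.9:
                chars[32] = "G"
            peps.append("".join(chars))
            labels.append(lab)
    return peps, np.array(labels)


class TestOptimizeEmbedding:
    CFG = dict(folds=3, seed=0, max_rounds=2, positions=[30, 32], pairs=[("G", "G"), ("A", "G")])

    def test_perfect_separation_is_a_fixed_point(self):
        # CV AUC is already 1.0, so no perturbation can be accepted
        pos = "A" * 30 + "K" + "A" * 30
        neg = "S" * 30 + "K" + "S" * 30
        peps = [pos] * 15 + [neg] * 15
        labels = np.array([1] * 15 + [0] * 15)
        init = ScoringModel(positives=[pos] * 15)
        res = optimize_embedding(peps, labels, init, OptimizeConfig(**self.CFG))
        assert res.initial_auc == 1.0
        np.testing.assert_array_equal(res.model.weights, init.weights)
        np.testing.assert_array_equal(res.model.matrix, init.matrix)

    def test_auc_never_decreases_on_motif_data(self):
        peps, labels = _motif_dataset()
        init = ScoringModel(positives=[p for p, l in zip(peps, labels) if l])
        res = optimize_embedding(peps, labels, init, OptimizeConfig(**self.CFG))
        assert res.final_auc >= res.initial_auc
        trace = np.array(res.auc_trace)
        assert (np.diff(trace) > 0).all() or len(trace) == 1

    def test_weights_stay_non_negative(self):
        peps, labels = _motif_dataset()
        init = ScoringModel(
            positives=[p for p, l in zip(peps, labels) if l],
            weights=np.full(61, 0.05),
        )
        res = optimize_embedding(peps, labels, init, OptimizeConfig(**self.CFG))
        assert (res.model.weights >= 0).all()


class TestSerialization:
    def test_roundtrip_preserves_model(self, tmp_path):
        model = ScoringModel(
            positives=[random_peptide() for _ in range(3)],
            weights=RNG.uniform(0, 2, 61),
            matrix=blosum62() + 1.0,
            plr_c=1.3,
        )
        save_scoring_model(model, tmp_path / "m.json")
        back = load_scoring_model(tmp_path / "m.json")
        np.testing.assert_array_equal(back.weights, model.weights)
        np.testing.assert_array_equal(back.matrix, model.matrix)
        assert back.positives == model.positives
        assert back.plr_c == model.plr_c
        p = random_peptide()
        assert embed(p, back) == pytest.approx(embed(p, model))
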