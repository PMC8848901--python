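import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guideforge.fixtures import make_training_set
from guideforge.scoring import (
    EncodingError,
    ScorerConfigError,
    ScoringConstants,
    SvrModel,
    TrainingError,
    TrainingSet,
    decode,
    encode,
    evaluate_logo,
    feature_rowspace,
    flat_length,
    identifiable_cosine,
    score_logistic,
    score_svr,
    train_svr,
)

contexts30 = st.text(alphabet="ACGT", min_size=30, max_size=30)


class TestEncoding:
    def test_homopolymer_columns(self):
        f = encode("A" * 30)
        assert f.first_order[:, 0].sum() == 30 and f.first_order.sum() == 30
        assert f.second_order[:, 0].sum() == 29 and f.second_order.sum() == 29

    @settings(max_examples=50, deadline=None)
    @given(ctx=contexts30)
    def test_one_hot_rows_and_bijection(self, ctx):
        f = encode(ctx)
        assert (f.first_order.sum(axis=1) == 1).all()
        assert (f.second_order.sum(axis=1) == 1).all()
        assert decode(f) == ctx

    def test_flat_vector_length(self):
        assert flat_length(30) == 584
        assert encode("A" * 30).flat_vector.shape == (584,)

    def test_n_rejected(self):
        with pytest.raises(EncodingError):
            encode("A" * 29 + "N")


class TestLogisticScorer:
    def test_zero_weight_low_gc_branch(self):
        # 40% GC guide portion -> k_low
        guide = "GCGCGCGC" + "AT" * 6  # 8 GC of 20
        ctx = "AAAAA" + guide + "AAAAA"
        expected = 1.0 / (1.0 + math.exp(-(0.59763615 - 0.2026259)))
        assert score_logistic(ctx) == pytest.approx(expected, abs=1e-12)

    def test_zero_weight_boundary_gc_takes_high_branch(self):
        guide = "GCGCGCGCGC" + "AT" * 5  # exactly 50% GC
        ctx = "AAAAA" + guide + "AAAAA"
        expected = 1.0 / (1.0 + math.exp(-(0.59763615 - 0.1665878)))
        assert score_logistic(ctx) == pytest.approx(expected, abs=1e-12)

    def test_gc_computed_on_guide_not_context(self):
        # flanks all GC must not flip the branch of an AT-rich guide
        guide = "AT" * 10
        ctx = "GGGGG" + guide + "CCCCC"
        expected = 1.0 / (1.0 + math.exp(-(0.59763615 - 0.2026259)))
        assert score_logistic(ctx) == pytest.approx(expected, abs=1e-12)

    def test_active_weight_increases_score(self):
        ctx = "ACGT" * 7 + "AC"
        base = score_logistic(ctx)
        c = ScoringConstants()
        c.w1[0, 0] += 10.0  # position 0 is 'A': active cell
        assert score_logistic(ctx, c) > base

    @settings(max_examples=50, deadline=None)
    @given(ctx=contexts30)
    def test_score_in_open_unit_interval(self, ctx):
        assert 0.0 < score_logistic(ctx) < 1.0

    def test_shape_mismatch_is_config_error(self):
        with pytest.raises(ScorerConfigError):
            ScoringConstants(w1=np.zeros((29, 4)))
        with pytest.raises(ScorerConfigError):
            score_logistic("A" * 31)

    def test_constants_from_file_dense_and_sparse(self, tmp_path):
        dense = tmp_path / "dense.json"
        w1 = np.zeros((30, 4)); w1[2, 1] = 0.5
        dense.write_text(json.dumps({"intercept": 0.1, "w1": w1.tolist()}))
        c = ScoringConstants.from_file(str(dense))
        assert c.intercept == 0.1 and c.w1[2, 1] == 0.5 and c.k_low == -0.2026259
        sparse = tmp_path / "sparse.json"
        sparse.write_text(json.dumps({"w2": [[3, 7, -1.25]]}))
        c2 = ScoringConstants.from_file(str(sparse))
        assert c2.w2[3, 7] == -1.25 and c2.w2.sum() == -1.25


class TestSvr:
    def test_degenerate_inputs_rejected(self):
        with pytest.raises(TrainingError):
            train_svr(TrainingSet(["A" * 30], ["g1"], np.array([0.5])))
        with pytest.raises(TrainingError):
            train_svr(TrainingSet(["A" * 30, "C" * 30], ["g1", "g1"], np.array([0.5, 0.6])))

    def test_rank_out_of_unit_interval_rejected(self):
        with pytest.raises(TrainingError):
            TrainingSet(["A" * 30, "C" * 30], ["g1", "g2"], np.array([0.5, 1.2]))

    def test_zero_model_scores_half_everywhere(self):
        model = SvrModel(weights=np.zeros(584), bias=0.5)
        assert score_svr("ACGT" * 7 + "GG", model) == 0.5

    def test_predictions_clipped(self):
        model = SvrModel(weights=np.full(584, 1.0), bias=0.0)
        assert score_svr("G" * 30, model) == 1.0
        model_neg = SvrModel(weights=np.full(584, -1.0), bias=0.0)
        assert score_svr("G" * 30, model_neg) == 0.0

    def test_length_mismatch_is_config_error(self):
        model = SvrModel(weights=np.zeros(100), bias=0.0)
        with pytest.raises(ScorerConfigError):
            score_svr("A" * 30, model)

    def test_duplicated_rows_give_same_model(self):
        ts, _ = make_training_set(n=200, seed=1, noise_sigma=0.0, n_groups=4)
        m1 = train_svr(ts, epsilon=0.01, seed=0)
        dup = TrainingSet(ts.contexts * 2, ts.gene_ids * 2, np.concatenate([ts.ranks, ts.ranks]))
        m2 = train_svr(dup, epsilon=0.01, seed=0)
        # duplication rescales the data term; with identical optima the fits
        # agree up to solver tolerance
        assert np.corrcoef(m1.weights, m2.weights)[0, 1] > 0.99

    def test_training_is_deterministic(self):
        ts, _ = make_training_set(n=300, seed=2, noise_sigma=0.05, n_groups=5)
        m1 = train_svr(ts, seed=0)
        m2 = train_svr(ts, seed=0)
        assert np.array_equal(m1.weights, m2.weights) and m1.bias == m2.bias

    def test_model_roundtrip(self, tmp_path):
        ts, _ = make_training_set(n=120, seed=4, noise_sigma=0.05, n_groups=4)
        m = train_svr(ts, seed=0)
        path = tmp_path / "model.json"
        m.save(str(path))
        back = SvrModel.load(str(path))
        assert np.allclose(back.weights, m.weights) and back.bias == m.bias
        assert back.trained_on == m.trained_on

    def test_parameter_recovery_small(self):
        """Moderate-n sanity version of the recovery experiment (the full
        n=2000 run lives in the acceptance suite)."""
        ts, w_true = make_training_set(n=800, seed=7, noise_sigma=0.05, n_groups=8)
        m = train_svr(ts, epsilon=0.01, seed=0)
        basis = feature_rowspace()
        assert identifiable_cosine(m.weights, w_true, basis) > 0.85
        preds = np.array([score_svr(c, m) for c in ts.contexts[:200]])
        assert np.corrcoef(preds, ts.ranks[:200])[0, 1] > 0.85


class TestLeaveOneGroupOut:
    def test_needs_three_groups(self):
        ts, _ = make_training_set(n=100, seed=1, noise_sigma=0.0, n_groups=2)
        with pytest.raises(TrainingError):
            evaluate_logo(ts)

    def test_noiseless_ranks_recovered(self):
        # fold training sets must comfortably exceed the 584-dim feature
        # space, otherwise the fit is underdetermined regardless of noise
        ts, _ = make_training_set(n=750, seed=3, noise_sigma=0.0, n_groups=5)
        res = evaluate_logo(ts, epsilon=0.01)
        assert res["pooled"]["r2"] > 0.9
        assert set(res["per_group"]) == {f"gene{i}" for i in range(1, 6)}

    def test_shuffled_labels_have_no_skill(self):
        ts, _ = make_training_set(n=450, seed=3, noise_sigma=0.0, n_groups=3)
        rng = np.random.default_rng(0)
        shuffled = ts.ranks.copy()
        rng.shuffle(shuffled)
        res = evaluate_logo(TrainingSet(ts.contexts, ts.gene_ids, shuffled), epsilon=0.01)
        assert res["pooled"]["r2"] < 0.1
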