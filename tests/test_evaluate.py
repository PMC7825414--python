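import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from backload.anthropometry import Anthropometry
from backload.estimator import fit
from backload.evaluate import (
    force_to_bw,
    mape_thresholded,
    moment_to_compression,
    permutation_importance,
    r2_score,
    rmse,
    wilcoxon_paired,
)


class TestR2:
    def test_hand_arithmetic_example(self):
        assert r2_score([1, 2, 3, 4], [1, 2, 3, 5]) == pytest.approx(0.8)

    def test_perfect_predictions(self):
        y = np.array([0.1, 0.4, -0.2])
        assert r2_score(y, y) == 1.0

    def test_mean_prediction_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert r2_score(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_zero_variance_target_raises(self):
        with pytest.raises(ValueError, match="variance"):
            r2_score(np.ones(5), np.ones(5))

    @given(shift=st.floats(-100, 100))
    def test_common_additive_shift_leaves_r2_unchanged(self, shift):
        y = np.array([0.0, 1.0, 2.0, 5.0])
        p = np.array([0.2, 1.1, 1.7, 4.5])
        assert r2_score(y + shift, p + shift) == pytest.approx(r2_score(y, p))


class TestRmse:
    COHORT = [Anthropometry("A", 79.0, 1.8)]

    def test_zero_error(self):
        y = np.array([0.1, 0.2])
        assert rmse(y, y, self.COHORT) == (0.0, 0.0)

    def test_constant_error_converts_with_mean_bwbh(self):
        y = np.zeros(100)
        p = np.full(100, 0.01)
        bwbh, nm = rmse(y, p, self.COHORT)
        assert bwbh == pytest.approx(0.01)
        assert nm == pytest.approx(0.01 * 79.0 * 9.81 * 1.8)  # ~13.95 Nm
        assert round(nm, 2) == 13.95

    def test_homogeneity(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=50)
        p = y + rng.normal(size=50) * 0.1
        b1, n1 = rmse(y, p, self.COHORT)
        b2, n2 = rmse(y, y + 2 * (p - y), self.COHORT)
        assert b2 == pytest.approx(2 * b1)
        assert n2 == pytest.approx(2 * n1)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rmse(np.array([]), np.array([]), self.COHORT)


class TestMape:
    def test_perfect_predictions(self):
        y = np.array([0.1, 0.2, 0.3])
        assert mape_thresholded(y, y) == 0.0

    def test_uniform_underestimate(self):
        y = np.array([0.1, 0.2, 0.4])
        assert mape_thresholded(y, 0.9 * y) == pytest.approx(10.0)

    def test_threshold_masks_low_moment_samples(self):
        y = np.array([0.01, 0.04, 0.2])
        p = np.array([5.0, 5.0, 0.1])  # wild errors below threshold are ignored
        assert mape_thresholded(y, p, threshold=0.05) == pytest.approx(50.0)

    def test_no_samples_above_threshold_raises(self):
        with pytest.raises(ValueError, match="threshold"):
            mape_thresholded(np.array([0.01]), np.array([0.01]))


class TestUnitConversions:
    def test_moment_arm_conversion(self):
        assert moment_to_compression(7.0) == pytest.approx(100.0)

    def test_recommended_compression_limit_in_bw(self):
        exact, rounded = force_to_bw(3400.0, 79.0)
        assert rounded == 4.4
        assert exact == pytest.approx(3400.0 / (79.0 * 9.81), abs=1e-9)
        assert exact == pytest.approx(4.3872, abs=5e-4)

    def test_distributed_error_in_bw(self):
        exact, rounded = force_to_bw(241.0, 79.0)
        assert rounded == 0.3
        assert exact == pytest.approx(0.3110, abs=5e-4)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            moment_to_compression(7.0, 0.0)
        with pytest.raises(ValueError):
            force_to_bw(100.0, 0.0)


class TestWilcoxon:
    def test_all_positive_differences_exact_p(self):
        a = np.arange(10) + 1.0
        b = a - np.linspace(0.1, 0.5, 10)
        # one-sided orderings of the signed-rank null: 2 / 2^10
        assert wilcoxon_paired(a, b) == pytest.approx(2.0 / 1024.0)

    def test_rank_balanced_differences_give_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        d = np.array([0.1, -0.2, -0.3, 0.4])  # signed ranks split 5 vs 5
        assert wilcoxon_paired(a + d, a) == pytest.approx(1.0)

    def test_identical_vectors_are_degenerate(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_paired(np.ones(6), np.ones(6))


class TestPermutationImportance:
    def test_constant_channel_has_zero_importance(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.normal(size=600), np.full(600, 2.0)])
        y = X[:, 0]
        model = fit(X, y)
        table = permutation_importance(model, X, y, repeats=5, seed=0,
                                       channel_names=["signal", "constant"])
        row = table.table.set_index("channel").loc["constant"]
        assert abs(row["delta_r2"]) < 1e-6

    def test_single_informative_channel_loses_everything_when_shuffled(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(1000, 1))
        y = X[:, 0]
        model = fit(X, y)
        baseline = r2_score(y, model.predict(X))
        table = permutation_importance(model, X, y, repeats=5, seed=0)
        # shuffling destroys all signal: the drop is at least the whole baseline
        # (a permuted perfect predictor scores about -1, so the drop approaches 2)
        assert table.table["delta_r2"].iloc[0] >= 0.9 * baseline

    def test_duplicated_channels_split_the_credit(self):
        """A shuffled twin leaves its copy intact, so each twin's drop is small."""
        rng = np.random.default_rng(2)
        s = rng.normal(size=1500)
        X = np.column_stack([s + 0.1 * rng.normal(size=1500),
                             s + 0.1 * rng.normal(size=1500),
                             rng.normal(size=1500)])
        y = s
        model = fit(X, y)
        table = permutation_importance(model, X, y, repeats=5, seed=0,
                                       channel_names=["twin_a", "twin_b", "noise"])
        joint = r2_score(y, model.predict(X))
        per = table.table.set_index("channel")["delta_r2"]
        # a lone informative channel drops ~2x the baseline when shuffled;
        # with a correlated twin standing in, each channel drops far less
        assert per["twin_a"] < joint
        assert per["twin_b"] < joint
        assert min(per["twin_a"], per["twin_b"]) < 0.5 * joint

    def test_ranking_is_a_permutation_of_channels(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(400, 4))
        y = X[:, 0] + 0.3 * X[:, 1]
        model = fit(X, y)
        names = ["a", "b", "c", "d"]
        table = permutation_importance(model, X, y, repeats=2, seed=0, channel_names=names)
        assert sorted(table.ranking) == sorted(names)
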