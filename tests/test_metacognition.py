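import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import simulate_rated_trials
from metaadvice import (
    ConfidenceCounts,
    ObserverParams,
    bin_confidence,
    clamp_negative_meta_d,
    counts_from_trials,
    estimable,
    fit_meta_d,
    fit_type1_sdt,
    mean_confidence,
)
from metaadvice.metacognition import (
    EstimabilityError,
    _neg_log_likelihood,
    type2_level_probabilities,
)
from metaadvice.staircase import InsufficientDataError


def frame_from_ratings(ratings):
    return pd.DataFrame(
        {
            "phase": "main",
            "majority_side": "A",
            "choice1": "A",
            "correct1": True,
            "confidence1": ratings,
        }
    )


class TestMeanConfidence:
    def test_constant_ratings(self):
        assert mean_confidence(frame_from_ratings([0.5] * 4)) == 0.5

    def test_arithmetic_mean(self):
        assert mean_confidence(frame_from_ratings([0.2, 0.4, 0.9])) == pytest.approx(0.5)

    def test_practice_trials_ignored(self, one_session):
        main = one_session[one_session["phase"] == "main"]
        assert mean_confidence(one_session) == pytest.approx(
            main["confidence1"].mean()
        )

    def test_no_rated_trials_raises(self):
        df = frame_from_ratings([0.5]).assign(phase="practice")
        with pytest.raises(InsufficientDataError):
            mean_confidence(df)


class TestBinning:
    @pytest.mark.parametrize(
        "rating,expected",
        [(0.0, 1), (1.0, 6), (0.49, 3), (0.5, 3), (0.51, 4), (1 / 6, 1)],
    )
    def test_equal_width_bins(self, rating, expected):
        assert bin_confidence([rating], 6)[0] == expected

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bin_confidence([1.2], 6)

    def test_rejects_single_level(self):
        with pytest.raises(ValueError):
            bin_confidence([0.5], 1)


class TestType1Fit:
    def make_counts(self, h_r2, h_total, f_r2, f_total, k=3):
        counts = np.zeros((2, 2, k))
        counts[1, 1, 0] = h_r2
        counts[1, 0, 0] = h_total - h_r2
        counts[0, 1, 0] = f_r2
        counts[0, 0, 0] = f_total - f_r2
        return ConfidenceCounts(counts)

    def test_chance(self):
        d, c = fit_type1_sdt(self.make_counts(50, 100, 50, 100), pad=0)
        assert d == pytest.approx(0.0, abs=1e-12)
        assert c == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_quantiles(self):
        # H=0.8, F=0.3: d' = z(0.8) - z(0.3), c = -(z(0.8)+z(0.3))/2
        d, c = fit_type1_sdt(self.make_counts(80, 100, 30, 100), pad=0)
        z = stats.norm.ppf
        assert d == pytest.approx(z(0.8) - z(0.3), abs=1e-9)
        assert c == pytest.approx(-0.5 * (z(0.8) + z(0.3)), abs=1e-9)

    def test_sign_symmetry_under_relabeling(self):
        d1, _ = fit_type1_sdt(self.make_counts(80, 100, 30, 100), pad=0)
        d2, _ = fit_type1_sdt(self.make_counts(30, 100, 80, 100), pad=0)
        assert d1 == pytest.approx(-d2, abs=1e-9)

    def test_missing_stimulus_class_raises(self):
        counts = np.zeros((2, 2, 3))
        counts[1, 1, 0] = 40
        counts[1, 0, 0] = 20
        with pytest.raises(InsufficientDataError):
            fit_type1_sdt(ConfidenceCounts(counts))


class TestMetaDFit:
    def test_probabilities_normalise(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            meta_d = rng.normal(0, 2)
            c_meta = rng.normal(0, 0.5)
            crit_r1 = c_meta - np.cumsum(rng.uniform(0.05, 1, 4))
            crit_r2 = c_meta + np.cumsum(rng.uniform(0.05, 1, 4))
            probs = type2_level_probabilities(meta_d, c_meta, crit_r1, crit_r2)
            assert np.allclose(probs.sum(axis=2), 1.0, atol=1e-8)

    def test_optimum_beats_random_starts(self):
        rng = np.random.default_rng(1)
        counts = ConfidenceCounts(rng.integers(2, 40, size=(2, 2, 4)).astype(float))
        fit = fit_meta_d(counts)
        padded = counts.padded()
        k = counts.n_levels
        best_random = np.inf
        for _ in range(200):
            x = np.concatenate(
                ([rng.uniform(-3, 3)], rng.uniform(-3, 1, 2 * (k - 1)))
            )
            best_random = min(
                best_random,
                _neg_log_likelihood(x, padded, fit.d_prime, fit.criterion),
            )
        assert -fit.log_likelihood <= best_random + 1e-6

    def test_efficiency_identity(self):
        rng = np.random.default_rng(2)
        counts = ConfidenceCounts(rng.integers(2, 40, size=(2, 2, 3)).astype(float))
        fit = fit_meta_d(counts)
        assert fit.efficiency * fit.d_prime == fit.meta_d

    def test_type2_criteria_ordered_around_scaled_criterion(self):
        rng = np.random.default_rng(3)
        counts = ConfidenceCounts(rng.integers(2, 40, size=(2, 2, 4)).astype(float))
        fit = fit_meta_d(counts)
        c_meta = fit.criterion * fit.efficiency
        r1 = np.array(fit.type2_criteria_r1)
        r2 = np.array(fit.type2_criteria_r2)
        assert (np.diff(r1) < 0).all() and (r1 < c_meta).all()
        assert (np.diff(r2) > 0).all() and (r2 > c_meta).all()

    def test_single_level_raises(self):
        counts = np.zeros((2, 2, 3))
        counts[:, :, 2] = [[30, 10], [10, 30]]
        with pytest.raises(EstimabilityError):
            fit_meta_d(ConfidenceCounts(counts))

    def test_efficiency_decreases_with_meta_noise(self):
        # mean fitted efficiency must be non-increasing in the generative
        # meta-level noise (here 40 simulated participants per level)
        means = []
        for noise in (0.0, 1.0, 2.0, 3.0):
            effs = []
            for i in range(40):
                params = ObserverParams(meta_noise_sd=noise)
                trials = simulate_rated_trials(params, 300, 18, seed=1000 + i)
                fit = fit_meta_d(counts_from_trials(trials, 6))
                effs.append(fit.efficiency)
            means.append(np.mean(effs))
        assert all(a >= b for a, b in zip(means, means[1:]))
        assert means[0] > means[-1] + 0.3


class TestEstimability:
    def test_extreme_raters_not_estimable(self):
        assert not estimable(frame_from_ratings([1.0] * 40))

    def test_spread_ratings_estimable(self, one_session):
        assert estimable(one_session)

    def test_missing_response_not_estimable(self):
        df = frame_from_ratings(list(np.linspace(0, 1, 40)))
        # every response is 'A': no type-2 data for R2
        assert not estimable(df)


class TestClamping:
    def test_negative_clamped_to_zero(self):
        rng = np.random.default_rng(7)
        # uniform random confidence but biased counts produce small meta-d;
        # force a negative fit by swapping confidence between correct/error
        for seed in range(20):
            counts = ConfidenceCounts(
                np.random.default_rng(seed).integers(1, 30, size=(2, 2, 3)).astype(float)
            )
            fit = fit_meta_d(counts)
            clamped = clamp_negative_meta_d(fit)
            if fit.meta_d < 0:
                assert clamped.meta_d == 0.0
                assert clamped.efficiency == 0.0
            else:
                assert clamped == fit
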