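import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metaadvice import (
    CohortSpec,
    ObserverParams,
    TaskConfig,
    generate_cohort,
    schedule_advice,
    simulate_confidence,
    simulate_decision,
    simulate_participant,
    simulate_post_advice,
)


class TestDecision:
    def test_chance_at_zero_signal(self):
        params = ObserverParams(sensitivity_slope=1e-9)
        rng = np.random.default_rng(0)
        correct = [
            simulate_decision(params, 20, rng)[0]
            == simulate_decision(params, 20, rng)[1]
            for _ in range(2000)
        ]
        # choices and majorities are independent at zero signal
        assert abs(np.mean(correct) - 0.5) < 0.05

    def test_accuracy_matches_normal_cdf(self):
        # d = slope * difference = 1.06 -> accuracy ~ Phi(0.53)
        params = ObserverParams(sensitivity_slope=1.06 / 20)
        rng = np.random.default_rng(1)
        n = 100_000
        correct = np.empty(n, dtype=bool)
        for i in range(n):
            majority, choice, _ = simulate_decision(params, 20, rng)
            correct[i] = choice == majority
        expected = stats.norm.cdf(0.53)
        assert abs(correct.mean() - expected) < 0.005

    def test_asymptotic_accuracy_at_large_signal(self):
        params = ObserverParams(sensitivity_slope=0.3)  # d = 6 at delta 20
        rng = np.random.default_rng(2)
        correct = [
            (lambda m, c, e: c == m)(*simulate_decision(params, 20, rng))
            for _ in range(2000)
        ]
        assert np.mean(correct) > 0.99


class TestConfidence:
    def test_confidence_always_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for bias in (-0.5, 0.0, 0.8):
            params = ObserverParams(confidence_bias=bias, meta_noise_sd=2.0)
            for _ in range(500):
                conf = simulate_confidence(params, rng.normal(0, 2), rng)
                assert 0.0 <= conf <= 1.0

    def test_degenerate_gain_collapses_ratings(self):
        params = ObserverParams(confidence_gain=1e-12, confidence_bias=0.0)
        rng = np.random.default_rng(4)
        confs = {
            round(simulate_confidence(params, rng.normal(), rng), 6)
            for _ in range(100)
        }
        assert confs == {0.0}

    def test_meta_noise_decouples_confidence_from_accuracy(self):
        # confidence-accuracy coupling must shrink as meta noise grows
        def coupling(noise_sd, seed):
            params = ObserverParams(meta_noise_sd=noise_sd)
            rng = np.random.default_rng(seed)
            confs, correct = [], []
            for _ in range(20_000):
                majority, choice, ev = simulate_decision(params, 18, rng)
                confs.append(simulate_confidence(params, ev, rng))
                correct.append(choice == majority)
            confs, correct = np.array(confs), np.array(correct)
            return confs[correct].mean() - confs[~correct].mean()

        assert coupling(0.0, 10) > coupling(3.0, 10) + 0.05


class TestAdviceSchedule:
    def test_exact_advice_count(self):
        rng = np.random.default_rng(5)
        plan = schedule_advice(80, 0.5, 0.7, rng)
        assert sum(given for given, _ in plan) == 40

    def test_perfect_advisor_always_correct(self):
        rng = np.random.default_rng(6)
        plan = schedule_advice(200, 1.0, 1.0, rng)
        assert all(correct for given, correct in plan if given)

    def test_no_advice_fraction_zero(self):
        rng = np.random.default_rng(7)
        plan = schedule_advice(80, 0.0, 0.7, rng)
        assert not any(given for given, _ in plan)


class TestPostAdvice:
    def test_agreeing_advice_zero_baseline_never_switches(self):
        params = ObserverParams(switch_baseline=0.0)
        rng = np.random.default_rng(8)
        assert not any(
            simulate_post_advice(params, 0.2, True, rng) for _ in range(500)
        )

    def test_advice_blind_agent_switches_equally(self):
        params = ObserverParams(advice_trust=0.0, switch_baseline=0.3)
        rng = np.random.default_rng(9)
        agree = np.mean(
            [simulate_post_advice(params, 0.5, True, rng) for _ in range(5000)]
        )
        conflict = np.mean(
            [simulate_post_advice(params, 0.5, False, rng) for _ in range(5000)]
        )
        assert abs(agree - conflict) < 0.03

    def test_low_confidence_switches_more_under_conflict(self):
        params = ObserverParams(advice_trust=1.0)
        rng = np.random.default_rng(10)
        low = np.mean(
            [simulate_post_advice(params, 0.1, False, rng) for _ in range(3000)]
        )
        high = np.mean(
            [simulate_post_advice(params, 0.9, False, rng) for _ in range(3000)]
        )
        assert low > high + 0.3


class TestSession:
    def test_trial_structure(self, one_session):
        df = one_session
        assert len(df) == 110
        main = df[df["phase"] == "main"]
        assert len(main) == 80
        assert main["confidence1"].notna().all()
        assert df[df["phase"] == "practice"]["confidence1"].isna().all()
        assert df[df["phase"] == "practice"]["feedback"].notna().all()
        assert main["feedback"].isna().all()
        assert main["advice_given"].sum() == 40

    def test_advice_fields_present_iff_advice_given(self, one_session):
        df = one_session
        adv = df["advice_given"].astype(bool)
        for col in ("advice_choice", "advice_correct", "advice_agrees",
                    "choice2", "switched", "confidence2"):
            assert df.loc[adv, col].notna().all()
            assert df.loc[~adv, col].isna().all()

    def test_switched_consistent_with_choices(self, one_session):
        adv = one_session[one_session["advice_given"].astype(bool)]
        assert (
            adv["switched"].astype(bool)
            == (adv["choice2"] != adv["choice1"])
        ).all()

    def test_fixed_seed_reproduces_records(self):
        params = ObserverParams()
        recs1 = simulate_participant(params, rng=np.random.default_rng(99))
        recs2 = simulate_participant(params, rng=np.random.default_rng(99))
        assert recs1 == recs2

    def test_no_advice_fields_when_fraction_zero(self):
        params = ObserverParams()
        task = TaskConfig(advice_fraction=0.0)
        recs = simulate_participant(params, task, rng=np.random.default_rng(1))
        df = pd.DataFrame(recs)
        assert not df["advice_given"].any()


class TestCohort:
    def test_default_cohort_size(self, small_cohort):
        participants, trials = generate_cohort(seed=3)
        assert len(participants) == 107
        assert set(participants["group"].value_counts().to_dict().items()) == {
            ("8-9", 30), ("12-13", 41), ("16-17", 36)
        }
        assert len(trials) == 107 * 110

    def test_same_seed_identical_tables(self):
        spec = CohortSpec()
        p1, t1 = generate_cohort(spec, seed=21)
        p2, t2 = generate_cohort(spec, seed=21)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_staircase_compensates_accuracy(self, small_cohort):
        _, trials = small_cohort
        main = trials[trials["phase"] == "main"]
        pooled = main["correct1"].astype(bool).mean()
        assert 0.66 <= pooled <= 0.74

    def test_confidence_in_unit_interval(self, small_cohort):
        _, trials = small_cohort
        conf = trials["confidence1"].dropna()
        assert ((conf >= 0) & (conf <= 1)).all()

    def test_advisor_accuracy_converges(self):
        rng = np.random.default_rng(12)
        plans = schedule_advice(100_000, 1.0, 0.7, rng)
        assert abs(np.mean([c for _, c in plans]) - 0.7) < 0.01
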