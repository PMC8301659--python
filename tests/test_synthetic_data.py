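import numpy as np
import pytest

from trialbf.bf_t import jzs_bf01
from trialbf.summary_stats import t_from_arm_summaries
from trialbf.synthetic_data import (
    CensoringError,
    Scenario,
    evidence_calibration,
    replicate_seed,
    simulate_binary_trial,
    simulate_continuous_trial,
    simulate_recovery_trial,
)


class TestContinuousTrial:
    def test_same_seed_bit_identical(self):
        a = simulate_continuous_trial(50, 60, 0.4, seed=123)
        b = simulate_continuous_trial(50, 60, 0.4, seed=123)
        assert np.array_equal(a.arm1, b.arm1) and np.array_equal(a.arm2, b.arm2)
        assert a.moment_summaries == b.moment_summaries
        assert a.quartile_summaries == b.quartile_summaries

    def test_null_trial_t_statistic_in_sampling_range(self):
        trial = simulate_continuous_trial(10_000, 10_000, 0.0, seed=7)
        cmp = t_from_arm_summaries(*trial.moment_summaries)
        assert abs(cmp.t) < 4

    def test_reconstructed_effect_unbiased(self):
        # mean reconstructed Cohen's d over replicates ~ true delta
        ds = []
        for k in range(1000):
            trial = simulate_continuous_trial(100, 100, 0.5, seed=replicate_seed(99, k))
            cmp = t_from_arm_summaries(*trial.moment_summaries)
            ds.append(cmp.t / np.sqrt(cmp.n_eff))
        assert abs(np.mean(ds) - 0.5) < 0.03

    def test_summaries_recomputable_from_raw(self):
        trial = simulate_continuous_trial(30, 30, 0.2, seed=5)
        m1 = trial.moment_summaries[0]
        assert m1.mean == pytest.approx(float(np.mean(trial.arm1)))
        assert m1.sd == pytest.approx(float(np.std(trial.arm1, ddof=1)))
        q1 = trial.quartile_summaries[0]
        assert q1.median == pytest.approx(float(np.median(trial.arm1)))


class TestBinaryTrial:
    def test_zero_probability_gives_zero_events(self):
        trial = simulate_binary_trial(100, 100, 0.0, 0.0, seed=3)
        assert trial.table.y1 == 0 and trial.table.y2 == 0

    def test_event_rate_law_of_large_numbers(self):
        rates = [
            simulate_binary_trial(500, 500, 0.1, 0.1, seed=replicate_seed(11, k)).table.y1 / 500
            for k in range(500)
        ]
        assert abs(np.mean(rates) - 0.1) < 0.01

    def test_solidarity_scale_difference_detected(self):
        # 8% vs 12% mortality at n=2700/arm: the BF should usually be
        # firmly pro-alternative
        bf01s = []
        for k in range(100):
            trial = simulate_binary_trial(2700, 2700, 0.08, 0.12, seed=replicate_seed(21, k))
            from trialbf.bf_contingency import mortality_bf

            bf01s.append(mortality_bf(trial.table, "indep_binomial").bf01)
        assert np.median(bf01s) < 1 / 3


class TestRecoveryTrial:
    def test_degenerate_distribution_recovers_medians_exactly(self):
        trial = simulate_recovery_trial(50, 50, 11.0, 15.0, 0.0, 1e9, seed=1)
        assert trial.quartile_summaries[0].median == pytest.approx(11.0)
        assert trial.quartile_summaries[1].median == pytest.approx(15.0)
        assert not trial.censored[0].any()

    def test_null_scenario_reconstructed_t_unbiased(self):
        # identical arms: the reconstructed t is centered on zero, with
        # roughly unit sampling spread (quartile estimators are a bit noisier
        # than moments, so the spread exceeds 1 slightly)
        ts = []
        for k in range(200):
            trial = simulate_recovery_trial(200, 200, 14, 14, 0.4, 60, seed=replicate_seed(31, k))
            ts.append(t_from_arm_summaries(*trial.quartile_summaries).t)
        assert abs(np.mean(ts)) < 0.25
        assert 0.8 < np.std(ts) < 2.0

    def test_censored_values_flagged_and_capped(self):
        trial = simulate_recovery_trial(300, 300, 11, 15, 0.6, 28, seed=2)
        assert trial.censored[0].any() or trial.censored[1].any()
        assert trial.arm1.max() <= 28 and trial.arm2.max() <= 28

    def test_overwhelming_censoring_rejected(self):
        # censor day barely above the median with huge spread: about half the
        # arm is censored, and this seed realizes >= 50% empirically
        with pytest.raises(CensoringError):
            simulate_recovery_trial(200, 200, 20.0, 20.0, 2.5, 20.05, seed=0)

    def test_actt_like_contrast_yields_pro_alternative_evidence(self):
        wins = 0
        reps = 60
        for k in range(reps):
            trial = simulate_recovery_trial(500, 500, 11, 15, 0.6, 28, seed=replicate_seed(41, k))
            cmp = t_from_arm_summaries(*trial.quartile_summaries)
            flipped = type(cmp)(t=-cmp.t, df=cmp.df, n1=cmp.n1, n2=cmp.n2)
            wins += jzs_bf01(flipped).bf01 < 1 / 3
        assert wins >= 0.9 * reps


class TestEvidenceCalibration:
    def test_single_rep_reproducible(self):
        sc = Scenario(kind="binary", params=dict(n1=100, n2=100, p1=0.1, p2=0.1))
        a = evidence_calibration(sc, reps=1, seed=5)
        b = evidence_calibration(sc, reps=1, seed=5)
        assert a.equals(b)
        assert len(a) == 1

    def test_null_continuous_scenario_favors_null(self):
        sc = Scenario(kind="continuous", params=dict(n1=200, n2=200, delta=0.0))
        table = evidence_calibration(sc, reps=100, seed=17)
        pro_null = table["freq_moderate_pro_null"][0] + table["freq_strong_pro_null"][0]
        pro_alt = (
            table["freq_moderate_pro_alternative"][0]
            + table["freq_strong_pro_alternative"][0]
        )
        assert pro_null > pro_alt

    def test_category_frequencies_sum_to_one(self):
        sc = Scenario(kind="recovery", params=dict(
            n1=100, n2=100, median1=11, median2=15, sigma_log=0.6, censor_day=28
        ))
        table = evidence_calibration(sc, reps=20, seed=8)
        freq_cols = [c for c in table.columns if c.startswith("freq_")]
        assert table[freq_cols].to_numpy().sum() == pytest.approx(1.0)

    def test_unknown_scenario_kind_rejected(self):
        with pytest.raises(ValueError):
            Scenario(kind="ordinal", params={})


def test_median_bf01_consistency_in_n():
    # under the null, evidence for the null accumulates with n;
    # under a large effect, evidence against it accumulates
    from trialbf.bf_contingency import mortality_bf

    def median_bf(delta, n, reps=120, root=61):
        vals = []
        for k in range(reps):
            trial = simulate_continuous_trial(n, n, delta, seed=replicate_seed(root + n, k))
            vals.append(jzs_bf01(t_from_arm_summaries(*trial.moment_summaries)).bf01)
        return float(np.median(vals))

    null_curve = [median_bf(0.0, n) for n in (50, 200, 1000)]
    assert null_curve[0] < null_curve[1] < null_curve[2]
    effect_curve = [median_bf(0.8, n) for n in (50, 200, 1000)]
    assert effect_curve[0] > effect_curve[1] > effect_curve[2]
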