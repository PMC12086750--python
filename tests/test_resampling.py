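"""Bootstrap verification and margin calibration."""

import math

import numpy as np
import pytest

from pninf import (
    ArmGenSpec,
    DesignError,
    SurvivalDataset,
    SurvivalGenSpec,
    bootstrap_verify,
    fixed_time_verify,
    gen_exponential_cohort,
    km_estimate,
    km_median,
    km_survival_at,
    margin_calibration,
)
from pninf.resampling import _km_median_rows, _km_survival_at_rows, _signed_diff

from conftest import uncensored_km_median


def _random_censored_rows(rng, rows, n):
    times = rng.exponential(12.0, size=(rows, n))
    cens = rng.exponential(20.0, size=(rows, n))
    obs = np.minimum(times, cens)
    events = (times <= cens).astype(int)
    return obs, events


class TestBatchKaplanMeier:
    def test_median_rows_match_lifelines_backed_estimator(self):
        # dual route: the vectorized product-limit used in the replicate
        # loop must agree with the curve-based estimator on censored data
        rng = np.random.default_rng(12)
        obs, events = _random_censored_rows(rng, 50, 80)
        batch = _km_median_rows(obs, events)
        for i in range(50):
            data = SurvivalDataset.from_arrays(["a"] * 80, obs[i], events[i])
            assert batch[i] == km_median(km_estimate(data, "a"))

    def test_survival_at_rows_match_curve(self):
        rng = np.random.default_rng(13)
        obs, events = _random_censored_rows(rng, 30, 60)
        batch = _km_survival_at_rows(obs, events, 10.0)
        for i in range(30):
            data = SurvivalDataset.from_arrays(["a"] * 60, obs[i], events[i])
            assert batch[i] == pytest.approx(
                km_survival_at(km_estimate(data, "a"), 10.0), abs=1e-12
            )

    def test_unreached_median_is_inf(self):
        obs = np.array([[1.0, 2.0, 3.0]])
        events = np.array([[0, 0, 1]])  # survival only drops to 2/3... stays > 1/2
        # with one event among three at risk reduced by prior censorings the
        # curve drops to 0 at t=3 (at risk 1), so the median *is* reached
        assert _km_median_rows(obs, events)[0] == 3.0
        events = np.array([[0, 0, 0]])
        assert np.isinf(_km_median_rows(obs, events)[0])

    def test_signed_diff_unreached_policy(self):
        m_app = np.array([np.inf, 5.0, np.inf])
        m_red = np.array([4.0, np.inf, np.inf])
        diff = _signed_diff(m_app, m_red)
        assert diff[0] == np.inf  # approved unreached, reduced finite: outside
        assert diff[1] == -np.inf  # reduced unreached: within the margin
        assert diff[2] == 0.0  # both unreached: no observable decrement


class TestBootstrapVerify:
    def test_same_seed_identical(self, phase3_scale_ipd):
        a = bootstrap_verify(phase3_scale_ipd, "approved", "control", 100, 1.5,
                             reps=500, seed=77)
        b = bootstrap_verify(phase3_scale_ipd, "approved", "control", 100, 1.5,
                             reps=500, seed=77)
        assert a.p_noninf == b.p_noninf and a.p_inf == b.p_inf
        assert np.array_equal(a.diffs_equivalence, b.diffs_equivalence)

    def test_huge_margin_saturates(self, phase3_scale_ipd):
        rep = bootstrap_verify(phase3_scale_ipd, "approved", "control", 100, 1e9,
                               reps=500, seed=1)
        assert rep.p_noninf == 1.0 and rep.p_inf == 0.0

    def test_counts_partition_reps(self, phase3_scale_ipd):
        rep = bootstrap_verify(phase3_scale_ipd, "approved", "control", 50, 1.5,
                               reps=400, seed=2)
        n_in = int(np.sum(rep.diffs_equivalence <= rep.margin))
        assert n_in + int(np.sum(rep.diffs_equivalence > rep.margin)) == rep.reps
        assert rep.p_noninf == n_in / rep.reps

    def test_matches_direct_simulation_oracle(self, phase3_scale_ipd):
        # oracle: draw *fresh* exponential samples at the case-study
        # medians (instead of resampling the finite source) and use the
        # order-statistic median; the bootstrap estimate must agree within
        # 3 combined (bootstrap MC + source-sampling + oracle MC) SEs
        reps = 3000
        rep = bootstrap_verify(phase3_scale_ipd, "approved", "control", 300, 1.5,
                               reps=reps, seed=5)
        rng = np.random.default_rng(99)
        scale_a, scale_c = 15.1 / math.log(2), 12.7 / math.log(2)

        def oracle(scale_red):
            meds_a = np.array([
                uncensored_km_median(rng.exponential(scale_a, 300))
                for _ in range(reps)
            ])
            meds_r = np.array([
                uncensored_km_median(rng.exponential(scale_red, 300))
                for _ in range(reps)
            ])
            return meds_a - meds_r

        p_ni_oracle = float(np.mean(oracle(scale_a) <= 1.5))
        p_if_oracle = float(np.mean(oracle(scale_c) > 1.5))

        # source-sampling SE: spread of the bootstrap estimate across
        # independently generated phase-III-scale sources
        ests_ni, ests_if = [], []
        for s in range(5):
            src = gen_exponential_cohort(SurvivalGenSpec(
                arms=(ArmGenSpec("approved", 15.1, 378),
                      ArmGenSpec("control", 12.7, 377)),
                seed=3000 + s,
            ))
            r = bootstrap_verify(src, "approved", "control", 300, 1.5,
                                 reps=1000, seed=50 + s)
            ests_ni.append(r.p_noninf)
            ests_if.append(r.p_inf)
        se_src_ni = float(np.std(ests_ni, ddof=1))
        se_src_if = float(np.std(ests_if, ddof=1))

        se_mc = math.sqrt(0.25 / reps)
        tol_ni = 3 * math.sqrt(rep.se_noninf**2 + se_src_ni**2 + se_mc**2)
        tol_if = 3 * math.sqrt(rep.se_inf**2 + se_src_if**2 + se_mc**2)
        assert abs(rep.p_noninf - p_ni_oracle) < tol_ni
        assert abs(rep.p_inf - p_if_oracle) < tol_if

    def test_oversampling_source_allowed(self, phase3_scale_ipd):
        rep = bootstrap_verify(phase3_scale_ipd, "approved", "control", 500, 1.5,
                               reps=200, seed=3)
        assert 0.0 <= rep.p_noninf <= 1.0


class TestMarginCalibration:
    def test_infinite_conventional_margin_gives_one(self, phase3_scale_ipd):
        rows = margin_calibration(phase3_scale_ipd, "approved", 100, [1.5],
                                  conventional_margin_hr=1e6, reps=500, seed=4)
        assert rows[0].conditional_prob_conventional == 1.0

    def test_probabilities_valid_and_counts_consistent(self, phase3_scale_ipd):
        rows = margin_calibration(phase3_scale_ipd, "approved", 200,
                                  [0.5, 1.5, 3.0], conventional_margin_hr=1.25,
                                  reps=1000, seed=8)
        counts = [r.n_practical_noninf for r in rows]
        assert counts == sorted(counts)  # larger margin, larger conditioning set
        for r in rows:
            if r.conditional_prob_conventional is not None:
                assert 0.0 <= r.conditional_prob_conventional <= 1.0

    def test_empty_conditioning_set_reported_as_none(self):
        # a reduced-source arm that is always far worse than the approved
        # arm leaves no replicate inside a tiny margin
        data = SurvivalDataset.from_arrays(
            ["approved"] * 5 + ["bad"] * 5,
            [100.0] * 5 + [1.0] * 5,
            [1] * 10,
        )
        rows = margin_calibration(data, "approved", 5, [1e-9],
                                  conventional_margin_hr=1.25, reps=200, seed=9,
                                  reduced_source_arm="bad")
        assert rows[0].n_practical_noninf == 0
        assert rows[0].conditional_prob_conventional is None

    def test_cross_check_against_direct_simulation(self):
        # equal-median arms drawn fresh each replicate: an independent
        # implementation of the same conditional probability
        n, reps = 120, 2000
        scale = 15.1 / math.log(2)
        hr_margin, alpha, margin = 1.30, 0.025, 1.5
        rng = np.random.default_rng(17)
        z = 1.959963984540054

        hits = sel = 0
        for _ in range(reps):
            ta = rng.exponential(scale, n)
            tr = rng.exponential(scale, n)
            diff = uncensored_km_median(ta) - uncensored_km_median(tr)
            if diff <= margin:
                sel += 1
                log_hr = math.log(n / tr.sum()) - math.log(n / ta.sum())
                if log_hr + z * math.sqrt(2 / n) < math.log(hr_margin):
                    hits += 1
        direct = hits / sel

        big = gen_exponential_cohort(SurvivalGenSpec(
            arms=(ArmGenSpec("approved", 15.1, 20_000),), seed=18))
        rows = margin_calibration(big, "approved", n, [margin], hr_margin,
                                  alpha=alpha, reps=reps, seed=19)
        got = rows[0].conditional_prob_conventional
        se = math.sqrt(direct * (1 - direct) / sel + got * (1 - got) / max(
            rows[0].n_practical_noninf, 1))
        assert abs(got - direct) < 3 * se + 0.01

    def test_invalid_hazard_margin_rejected(self, phase3_scale_ipd):
        with pytest.raises(DesignError):
            margin_calibration(phase3_scale_ipd, "approved", 100, [1.5],
                               conventional_margin_hr=0.9)


class TestFixedTimeVerify:
    def test_saturated_margin(self, phase3_scale_ipd):
        rep = fixed_time_verify(phase3_scale_ipd, "approved", "control", 100,
                                12.0, 1.0, reps=300, seed=1)
        assert rep.p_noninf == 1.0

    def test_same_seed_identical(self, phase3_scale_ipd):
        a = fixed_time_verify(phase3_scale_ipd, "approved", "control", 100,
                              12.0, 0.05, reps=300, seed=21)
        b = fixed_time_verify(phase3_scale_ipd, "approved", "control", 100,
                              12.0, 0.05, reps=300, seed=21)
        assert a.p_noninf == b.p_noninf and a.p_inf == b.p_inf

    def test_t_star_beyond_follow_up_rejected(self, phase3_scale_ipd):
        with pytest.raises(DesignError):
            fixed_time_verify(phase3_scale_ipd, "approved", "control", 100,
                              1e6, 0.05)

    def test_equal_median_arms_match_direct_oracle(self):
        # both simulated arms from the same source: compare the landmark
        # difference probability with fresh-draw simulation
        n, reps, t_star, margin = 200, 2000, 12.0, 0.05
        src = gen_exponential_cohort(SurvivalGenSpec(
            arms=(ArmGenSpec("approved", 15.1, 20_000),
                  ArmGenSpec("control", 12.7, 377)), seed=23))
        rep = fixed_time_verify(src, "approved", "control", n, t_star, margin,
                                reps=reps, seed=24)
        rng = np.random.default_rng(25)
        scale = 15.1 / math.log(2)
        s_a = np.mean(rng.exponential(scale, (reps, n)) > t_star, axis=1)
        s_r = np.mean(rng.exponential(scale, (reps, n)) > t_star, axis=1)
        direct = float(np.mean(s_a - s_r <= margin))
        se = math.sqrt(rep.se_noninf**2 + direct * (1 - direct) / reps)
        # the 20k-patient source makes source-sampling error negligible
        assert abs(rep.p_noninf - direct) < 3 * se + 0.01
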