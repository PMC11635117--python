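"""Survival metrics against hand-computed and brute-force oracles."""

import numpy as np
import pytest

from deeppath.survival import (
    SurvivalData,
    concordance_index,
    cox_hr,
    km_estimate,
    logrank,
    optimal_cutoff,
    time_dependent_auc,
)


class TestKaplanMeier:
    def test_two_events_product_limit_by_hand(self):
        km = km_estimate(SurvivalData(time=[1.0, 2.0], event=[1, 1]))
        assert np.isclose(km.S(1.0), 0.5)
        assert np.isclose(km.S(2.0), 0.0)
        assert km.S(0.5) == 1.0

    def test_all_censored_gives_unit_survival(self):
        km = km_estimate(SurvivalData(time=[3.0, 5.0, 9.0], event=[0, 0, 0]))
        assert np.allclose(km.survival, 1.0)

    def test_non_increasing_on_random_data(self, rng):
        t = rng.exponential(10, 50) + 0.1
        e = rng.integers(0, 2, 50)
        km = km_estimate(SurvivalData(time=t, event=e))
        assert np.all(np.diff(km.survival) <= 1e-12)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = np.sort(rng.exponential(5, 30)) + 0.1
        km = km_estimate(SurvivalData(time=t, event=np.ones(30, dtype=int)))
        for q in (t[5], t[15], t[27]):
            assert np.isclose(km.S(q), (t > q).mean(), atol=1e-12)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            SurvivalData(time=[0.0, 1.0], event=[1, 1])


def _logrank_oracle(t1, e1, t2, e2):
    """Observed-minus-expected over per-event-time 2x2 tables."""
    times = sorted({t for t, e in zip(list(t1) + list(t2),
                                      list(e1) + list(e2)) if e})
    O_E, V = 0.0, 0.0
    for t in times:
        n1 = sum(x >= t for x in t1)
        n2 = sum(x >= t for x in t2)
        d1 = sum(x == t and e for x, e in zip(t1, e1))
        d2 = sum(x == t and e for x, e in zip(t2, e2))
        n, d = n1 + n2, d1 + d2
        if n < 2:
            continue
        O_E += d1 - d * n1 / n
        V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return O_E**2 / V


class TestLogrank:
    def test_identical_groups_not_significant(self):
        g = SurvivalData(time=[1, 2, 3.0], event=[1, 1, 1])
        chi2, p = logrank(g, g)
        assert chi2 < 1e-9 and p > 0.99

    def test_matches_two_by_two_table_oracle(self):
        t1, e1 = [1.0, 2.0, 3.0], [1, 1, 1]
        t2, e2 = [4.0, 5.0, 6.0], [1, 1, 1]
        chi2, _ = logrank(SurvivalData(t1, e1), SurvivalData(t2, e2))
        assert np.isclose(chi2, _logrank_oracle(t1, e1, t2, e2), atol=1e-8)

    def test_symmetric_under_label_swap(self, rng):
        a = SurvivalData(rng.exponential(5, 20) + 0.1, rng.integers(0, 2, 20))
        b = SurvivalData(rng.exponential(9, 25) + 0.1, rng.integers(0, 2, 25))
        assert np.isclose(logrank(a, b)[0], logrank(b, a)[0], atol=1e-10)

    def test_no_events_warns_and_returns_null(self):
        a = SurvivalData([1.0, 2.0], [0, 0])
        b = SurvivalData([3.0, 4.0], [0, 0])
        with pytest.warns(UserWarning):
            chi2, p = logrank(a, b)
        assert chi2 == 0.0 and p == 1.0


class TestCoxHR:
    def _simulate(self, hr, n, seed, censor_scale=40.0):
        rng = np.random.default_rng(seed)
        group = rng.integers(0, 2, n)
        lam = 0.05 * hr**group
        t = rng.exponential(1 / lam)
        c = rng.exponential(censor_scale, n)
        return SurvivalData(np.minimum(t, c) + 1e-9, (t <= c).astype(int)), group

    def test_recovers_doubled_hazard(self):
        d, g = self._simulate(2.0, 500, seed=0)
        res = cox_hr(d, g)
        assert 1.7 <= res.hr <= 2.3
        assert res.ci95[0] <= res.hr <= res.ci95[1]

    def test_group_swap_inverts_hr(self):
        d, g = self._simulate(2.0, 200, seed=1)
        r1, r2 = cox_hr(d, g), cox_hr(d, 1 - g)
        assert np.isclose(r1.hr, 1 / r2.hr, rtol=1e-6)

    def test_null_ci_covers_one_in_most_replicates(self):
        cover = 0
        for seed in range(100):
            d, g = self._simulate(1.0, 80, seed=seed)
            res = cox_hr(d, g)
            cover += res.ci95[0] <= 1.0 <= res.ci95[1]
        assert cover >= 90

    def test_complete_separation_flagged(self):
        d = SurvivalData(time=[1, 2, 3, 10, 11, 12.0],
                         event=[1, 1, 1, 0, 0, 0])
        res = cox_hr(d, np.array([1, 1, 1, 0, 0, 0]))
        assert res.separated
        assert res.ci95 == (0.0, float("inf"))


class TestConcordance:
    def test_perfect_and_inverted_ranking(self):
        d = SurvivalData(time=[1, 2, 3.0], event=[1, 1, 1], risk=[3, 2, 1.0])
        assert concordance_index(d) == 1.0
        d_rev = SurvivalData(time=[1, 2, 3.0], event=[1, 1, 1], risk=[1, 2, 3.0])
        assert concordance_index(d_rev) == 0.0

    def test_matches_all_pairs_enumeration_with_censoring(self):
        t = [2.0, 4.0, 3.0, 5.0, 1.0]
        e = [1, 0, 1, 1, 1]
        r = [0.9, 0.1, 0.5, 0.2, 0.8]
        d = SurvivalData(t, e, r)
        conc = comp = 0.0
        for i in range(5):
            for j in range(5):
                if t[i] < t[j] and e[i]:
                    comp += 1
                    conc += (r[i] > r[j]) + 0.5 * (r[i] == r[j])
        assert np.isclose(concordance_index(d), conc / comp)

    def test_complement_symmetry(self, rng):
        t = rng.exponential(5, 40) + 0.1
        e = rng.integers(0, 2, 40)
        r = rng.standard_normal(40)
        c1 = concordance_index(SurvivalData(t, e, r))
        c2 = concordance_index(SurvivalData(t, e, -r))
        assert np.isclose(c1, 1 - c2, atol=1e-12)

    def test_no_events_undefined(self):
        with pytest.raises(ValueError):
            concordance_index(SurvivalData([1.0, 2.0], [0, 0], [0.1, 0.2]))


class TestTimeDependentAUC:
    def test_risk_equals_negative_time_is_perfect(self, rng):
        t = rng.exponential(10, 100) + 0.1
        d = SurvivalData(t, np.ones(100, dtype=int), -t)
        auc = time_dependent_auc(d, [np.median(t)])
        assert np.isclose(auc[float(np.median(t))], 1.0)

    def test_random_risk_near_half(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(10, 1000) + 0.1
        d = SurvivalData(t, np.ones(1000, dtype=int), rng.standard_normal(1000))
        auc = list(time_dependent_auc(d, [10.0]).values())[0]
        assert abs(auc - 0.5) < 0.05

    def test_no_censoring_reduces_to_binary_auc(self):
        rng = np.random.default_rng(12)
        t = rng.exponential(10, 200) + 0.1
        r = -t + rng.standard_normal(200) * 3
        d = SurvivalData(t, np.ones(200, dtype=int), r)
        horizon = float(np.quantile(t, 0.4))
        auc = time_dependent_auc(d, [horizon])[horizon]
        from sklearn.metrics import roc_auc_score

        binary = roc_auc_score((t <= horizon).astype(int), r)
        assert np.isclose(auc, binary, atol=1e-10)

    def test_degenerate_horizons_rejected(self):
        d = SurvivalData([1.0, 2.0, 3.0], [1, 1, 1], [3, 2, 1.0])
        with pytest.raises(ValueError, match="controls"):
            time_dependent_auc(d, [10.0])
        with pytest.raises(ValueError, match="cases"):
            time_dependent_auc(d, [0.5])


class TestOptimalCutoff:
    def _bimodal(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        half = n // 2
        risk = np.concatenate([rng.normal(-2, 0.3, half), rng.normal(2, 0.3, half)])
        lam = np.where(risk > 0, 0.25, 0.05)  # 5-fold hazard difference
        t = rng.exponential(1 / lam)
        c = rng.exponential(40, n)
        return SurvivalData(np.minimum(t, c) + 1e-9, (t <= c).astype(int), risk)

    def test_cutoff_separates_the_modes(self):
        d = self._bimodal()
        cut = optimal_cutoff(d)
        # threshold lies between the mode centers and the induced split
        # agrees with the true mode membership for nearly all patients
        assert -2.0 < cut.threshold < 2.0
        agreement = (cut.high_mask == (d.risk > 0)).mean()
        assert agreement >= 0.9

    def test_identical_risks_rejected(self):
        d = SurvivalData(np.arange(1.0, 13.0), np.ones(12, dtype=int),
                         np.full(12, 3.3))
        with pytest.raises(ValueError):
            optimal_cutoff(d)

    def test_split_invariant_to_monotone_transform(self):
        d = self._bimodal(seed=5)
        cut1 = optimal_cutoff(d)
        d2 = SurvivalData(d.time, d.event, np.exp(0.5 * d.risk))
        cut2 = optimal_cutoff(d2)
        assert np.array_equal(cut1.high_mask, cut2.high_mask)


class TestCrossChecks:
    def test_logrank_equals_cox_score_test_small_sample(self):
        # on tie-free data the log-rank statistic is the Cox score test
        t1, e1 = [1.1, 2.3, 4.7, 8.1], [1, 1, 0, 1]
        t2, e2 = [3.2, 5.5, 6.8, 9.9], [1, 0, 1, 1]
        chi2, _ = logrank(SurvivalData(t1, e1), SurvivalData(t2, e2))
        ref = _logrank_oracle(t1, e1, t2, e2)
        assert np.isclose(chi2, ref, atol=1e-8)

    def test_parameter_recovery_within_three_se(self):
        rng = np.random.default_rng(100)
        hits = 0
        reps = 100
        for _ in range(reps):
            group = rng.integers(0, 2, 120)
            lam = 0.05 * np.exp(0.7 * group)
            t = rng.exponential(1 / lam)
            c = rng.exponential(40, 120)
            d = SurvivalData(np.minimum(t, c) + 1e-9, (t <= c).astype(int))
            res = cox_hr(d, group)
            if res.separated:
                continue
            hits += abs(res.log_hr - 0.7) <= 3 * res.se_log_hr
        assert hits / reps >= 0.95
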