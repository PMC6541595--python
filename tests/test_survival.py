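import itertools

import numpy as np
import pytest
from lifelines import KaplanMeierFitter

from cyclotrace.datamodel import Condition
from cyclotrace.survival import (
    generation_fraction,
    km_estimate,
    km_inputs,
    km_median_by_generation,
    logrank_test,
    mann_whitney,
)
from tests.conftest import make_records


class TestKMEstimate:
    def test_uncensored_hand_example(self):
        curve = km_estimate([2, 4, 6, 8], [True] * 4)
        np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])
        assert curve.median == 4.0

    def test_one_censor_hand_example(self):
        curve = km_estimate([2, 4, 6], [True, False, True])
        np.testing.assert_allclose(curve.times, [2, 6])
        np.testing.assert_allclose(curve.survival, [2 / 3, 0.0])
        assert curve.median == 6.0

    def test_empty_and_bad_inputs(self):
        with pytest.raises(ValueError):
            km_estimate([], [])
        with pytest.raises(ValueError):
            km_estimate([1, 2], [True])
        with pytest.raises(ValueError):
            km_estimate([0.0, 1.0], [True, True])

    def test_all_censored_null_median(self):
        curve = km_estimate([5, 6, 7], [False, False, False])
        assert len(curve.times) == 0  # S stays at 1 with no events
        assert curve.median is None

    def test_zero_censoring_matches_empirical_survival(self):
        rng = np.random.default_rng(0)
        x = rng.gamma(4, 2, size=200)
        curve = km_estimate(x, np.ones(200, bool))
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(np.mean(x > t))
        # median equals inf{t: F(t) >= 0.5}
        assert curve.median == np.sort(x)[99 if 200 % 2 == 0 else 100]

    def test_early_censor_before_first_event_changes_nothing(self):
        base = km_estimate([2, 4, 6], [True] * 3)
        more = km_estimate([2, 4, 6, 1.5], [True, True, True, False])
        np.testing.assert_allclose(base.survival, more.survival)
        np.testing.assert_allclose(base.times, more.times)

    def test_late_censor_adds_no_event_steps(self):
        base = km_estimate([2, 4, 6], [True] * 3)
        more = km_estimate([2, 4, 6, 99], [True, True, True, False])
        np.testing.assert_allclose(base.times, more.times)
        assert more.at_risk[0] == 4
        assert more.events.sum() == base.events.sum()

    def test_matches_lifelines(self):
        rng = np.random.default_rng(42)
        dur = rng.gamma(5, 2, 300).round(1) + 0.1
        obs = rng.uniform(size=300) < 0.7
        ours = km_estimate(dur, obs)
        kmf = KaplanMeierFitter().fit(dur, obs)
        theirs = kmf.survival_function_at_times(ours.times).to_numpy()
        np.testing.assert_allclose(ours.survival, theirs, atol=1e-10)
        assert ours.median == pytest.approx(kmf.median_survival_time_)


def test_km_median_by_generation_flat_when_no_shrink():
    rng = np.random.default_rng(1)
    rows = []
    for gen in (2, 3, 4):
        for i in range(120):
            cc = float(np.round(rng.lognormal(np.log(13), 0.15) * 4) / 4)
            rows.append({
                "cell_id": f"g{gen}i{i}", "generation": gen, "complete": True,
                "cc_l_h": cc, "birth_time_h": 5.0, "end_time_h": 5.0 + cc,
            })
    rec = make_records(rows)
    med = km_median_by_generation(rec, "cc_l")
    vals = [m for m, _ in med.values()]
    assert max(vals) - min(vals) <= 0.75
    for m, (lo, hi) in med.values():
        assert lo <= m <= hi


def test_km_median_by_generation_small_stratum_omitted():
    rows = [{"cell_id": f"c{i}", "generation": 2, "complete": True,
             "cc_l_h": 10.0 + 0.25 * i, "birth_time_h": 1.0,
             "end_time_h": 11.0} for i in range(12)]
    rows.append({"cell_id": "lone", "generation": 3, "complete": True,
                 "cc_l_h": 9.0, "birth_time_h": 1.0, "end_time_h": 10.0})
    rec = make_records(rows)
    with pytest.warns(UserWarning, match="omitted"):
        med = km_median_by_generation(rec, "cc_l")
    assert set(med) == {2}


def test_km_inputs_excludes_gen1_and_apoptosis():
    rows = [
        {"cell_id": "f", "generation": 1, "complete": False,
         "birth_time_h": np.nan, "end_time_h": 45.0},
        {"cell_id": "a", "generation": 2, "complete": True, "cc_l_h": 10.0,
         "birth_time_h": 10.0, "end_time_h": 20.0},
        {"cell_id": "b", "generation": 2, "complete": False, "fate": "CENSORED_END",
         "birth_time_h": 40.0, "end_time_h": 45.0},
        {"cell_id": "c", "generation": 2, "complete": False, "fate": "APOPTOSIS",
         "birth_time_h": 30.0, "end_time_h": 40.0},
    ]
    inputs = km_inputs(make_records(rows))
    assert set(inputs["cell_id"]) == {"a", "b"}
    row_b = inputs.set_index("cell_id").loc["b"]
    assert row_b["duration"] == 5.0 and not row_b["observed"]


class TestLogrank:
    def test_identical_groups(self):
        d = [2.0, 4, 6, 8]
        o = [True] * 4
        stat, p = logrank_test(d, o, d, o)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_large_shift_significant(self):
        rng = np.random.default_rng(2)
        a = rng.gamma(20, 0.5, 100)
        b = a + 5.0
        stat, p = logrank_test(a, np.ones(100, bool), b, np.ones(100, bool))
        assert p < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([], [], [1.0], [True])

    def test_permutation_oracle(self):
        # independent oracle: permutation null of the log-rank statistic
        # on a 12-cell toy input, all events observed
        durations = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12.0])
        labels = np.array([0, 1] * 6)

        def logrank_stat(dur, grp):
            # all observed, distinct times: hypergeometric variance terms
            order = np.argsort(dur)
            g = grp[order]
            n = len(dur)
            n1 = np.cumsum(g[::-1])[::-1]  # group-1 at risk at each event
            nt = n - np.arange(n)
            o1 = g
            e1 = n1 / nt
            v = (n1 / nt) * (1 - n1 / nt)
            return (o1 - e1).sum() ** 2 / v[:-1].sum()

        obs_stat = logrank_stat(durations, labels)
        stat, p_chi2 = logrank_test(
            durations[labels == 0], np.ones(6, bool),
            durations[labels == 1], np.ones(6, bool),
        )
        assert obs_stat == pytest.approx(stat, rel=1e-6)
        rng = np.random.default_rng(3)
        n_perm = 100_000
        exceed = 0
        for _ in range(n_perm):
            exceed += logrank_stat(durations, rng.permutation(labels)) >= obs_stat - 1e-12
        p_perm = exceed / n_perm
        # the asymptotic chi-square p differs from the exact discrete
        # permutation null by a few percent at n=12; allow for both
        mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / n_perm) + 0.035
        assert abs(p_perm - p_chi2) <= mc_err


class TestMannWhitney:
    def test_complete_separation_u_zero(self):
        u, _ = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_equal_samples_p_one(self):
        _, p = mann_whitney([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert p == pytest.approx(1.0)

    def test_exact_small_sample_p_third(self):
        _, p = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert p == pytest.approx(1 / 3)

    def test_tie_corrected_u_equals_brute_force(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 20, 40) * 0.25
        b = rng.integers(0, 20, 35) * 0.25
        u, _ = mann_whitney(a, b)
        brute = sum(
            1.0 if x > y else (0.5 if x == y else 0.0)
            for x, y in itertools.product(a, b)
        )
        assert u == pytest.approx(brute)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestGenerationFraction:
    def test_all_gen1(self):
        rec = make_records([{"cell_id": f"c{i}", "generation": 1} for i in range(5)])
        assert generation_fraction(rec, 5) == 0.0

    def test_two_of_ten(self):
        rows = [{"cell_id": f"c{i}", "generation": 5 if i < 2 else 2}
                for i in range(10)]
        assert generation_fraction(make_records(rows), 5) == pytest.approx(20.0)

    def test_condition_filter(self):
        rows = [
            {"cell_id": "a", "generation": 5, "condition": "Diff"},
            {"cell_id": "b", "generation": 2, "condition": "Diff"},
            {"cell_id": "c", "generation": 2, "condition": "2i+LIF"},
        ]
        rec = make_records(rows)
        assert generation_fraction(rec, 5, Condition.DIFF) == pytest.approx(50.0)
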