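"""ICC via ANOVA decomposition, odd-even internal consistency, and
within- vs between-subject similarity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from condrel import (
    CohortConfig,
    VarianceComponents,
    apply_trial_exclusions,
    compare_similarity,
    icc,
    icc_accumulation,
    internal_consistency_odd_even,
    simulate_cohort,
    true_icc,
    within_between_similarity,
)


def cs_trials(values_by_participant, timepoint="T0", phase="ACQ", stimulus="CSP"):
    rows = []
    for pid, vals in values_by_participant.items():
        for i, v in enumerate(vals):
            rows.append({"participant": pid, "timepoint": timepoint, "day": 1,
                         "phase": phase, "stimulus": stimulus, "trial": i + 1,
                         "value": v, "valid": True, "role": "retained"})
    return pd.DataFrame(rows)


class TestICC:
    def test_hand_anova_example(self):
        x = [[1, 2], [3, 4], [5, 6], [7, 8]]
        con = icc(x, "con")
        assert con.estimate == pytest.approx(1.0)
        ab = icc(x, "abs")
        assert ab.estimate == pytest.approx(0.9302, abs=1e-4)
        assert (ab.msr, ab.msc, ab.mse) == pytest.approx((40 / 3, 2.0, 0.0))

    def test_perfect_agreement(self):
        x = np.column_stack([np.arange(5.0), np.arange(5.0)])
        assert icc(x, "abs").estimate == pytest.approx(1.0)
        assert icc(x, "con").estimate == pytest.approx(1.0)

    def test_negative_estimates_not_truncated(self):
        x = np.array([[1, 4.1], [2, 3.2], [3, 2.3], [4, 1.4], [2.5, 2.0]])
        assert icc(x, "con").estimate < 0

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=(10, 2)) + rng.normal(size=(10, 1))
            for typ in ("abs", "con"):
                r = icc(x, typ)
                assert r.ci_low <= r.estimate <= r.ci_high <= 1.0

    def test_consistency_at_least_absolute_under_session_shift(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=(12, 2)) + rng.normal(size=(12, 1))
            x[:, 1] += 1.0  # systematic shift: MSC > MSE territory
            a, c = icc(x, "abs"), icc(x, "con")
            if c.msc >= c.mse and c.msr >= c.mse:
                # a session shift can only lower absolute agreement
                assert c.estimate >= a.estimate - 1e-12
            if abs(c.msc - c.mse) < 1e-12:
                assert c.estimate == pytest.approx(a.estimate, abs=1e-9)

    def test_listwise_deletion_and_small_n_error(self):
        x = np.array([[1.0, 2.0], [np.nan, 3.0], [2.0, 2.5]])
        with pytest.raises(ValueError, match="at least 3"):
            icc(x, "abs")

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            icc(np.ones((5, 2)), "abs")

    def test_matches_reference_implementation(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(123)
        for _ in range(25):
            n = int(rng.integers(5, 30))
            x = rng.normal(size=(n, 2)) + rng.normal(size=(n, 1))
            df = pd.DataFrame({"s": np.repeat(np.arange(n), 2),
                               "r": np.tile([0, 1], n), "y": x.ravel()})
            ref = pg.intraclass_corr(df, targets="s", raters="r", ratings="y").set_index("Type")
            assert icc(x, "abs").estimate == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-6)
            assert icc(x, "con").estimate == pytest.approx(ref.loc["ICC(C,1)", "ICC"], abs=1e-6)


class TestICCAccumulation:
    def _cohort(self, sigma_ss=0.0, sigma_t=1.0, n=500, seed=0):
        from condrel.paradigm import ParadigmSpec, PhaseTrials

        par = ParadigmSpec(phases=("ACQ",), trials_per_phase={"ACQ": PhaseTrials(14, 0, 0)},
                           day_of_phase={"ACQ": 1})
        comp = VarianceComponents(mu=10, sigma_subject=1.0, sigma_subject_session=sigma_ss,
                                  sigma_trial=sigma_t, zero_p=0)
        cfg = CohortConfig(n, paradigm=par, components={s: comp for s in ("CSP", "CSM", "US")},
                           seed=seed, rating_means={})
        scr, _ = simulate_cohort(cfg)
        return apply_trial_exclusions(scr)

    def test_curve_length_equals_retained_trials(self):
        table = self._cohort(n=20)
        curve = icc_accumulation(table, "ACQ", "CSP", "con")
        assert len(curve) == 13

    def test_noise_free_curve_is_all_ones(self):
        from condrel.paradigm import ParadigmSpec, PhaseTrials

        par = ParadigmSpec(phases=("ACQ",), trials_per_phase={"ACQ": PhaseTrials(14, 0, 0)},
                           day_of_phase={"ACQ": 1})
        comp = VarianceComponents(mu=5, sigma_subject=1.0, sigma_subject_session=0,
                                  sigma_trial=0, zero_p=0)
        cfg = CohortConfig(10, paradigm=par, components={s: comp for s in ("CSP", "CSM", "US")},
                           seed=1, rating_means={})
        scr, _ = simulate_cohort(cfg)
        curve = icc_accumulation(apply_trial_exclusions(scr), "ACQ", "CSP", "con")
        assert all(r.estimate == pytest.approx(1.0) for r in curve)

    def test_curve_tracks_closed_form(self):
        """Averaging over 5 cohorts of n=500; true ICC at m trials is
        sigma_s^2 / (sigma_s^2 + sigma_t^2/m)."""
        curves = []
        for seed in range(5):
            table = self._cohort(sigma_ss=0.0, sigma_t=1.0, n=500, seed=100 + seed)
            curves.append([r.estimate for r in icc_accumulation(table, "ACQ", "CSP", "con")])
        mean_curve = np.mean(curves, axis=0)
        comp = VarianceComponents(sigma_subject=1.0, sigma_subject_session=0.0, sigma_trial=1.0)
        for m, est in enumerate(mean_curve, start=1):
            assert est == pytest.approx(true_icc(comp, m), abs=0.05)
        assert mean_curve[0] == pytest.approx(0.5, abs=0.05)


class TestInternalConsistency:
    def test_odd_even_split_sizes_for_13_trials(self):
        rng = np.random.default_rng(0)
        table = cs_trials({f"P{i}": rng.random(13) for i in range(8)})
        res = internal_consistency_odd_even(table, "ACQ", "CSP", "T0")
        assert (res.n_trials_odd, res.n_trials_even) == (7, 6)

    def test_known_pearson_from_split_means(self):
        # participants whose odd/even means are [1,2,3,4] and [2,1,4,3] -> r = 0.6
        table = cs_trials({"P1": [1, 2], "P2": [2, 1], "P3": [3, 4], "P4": [4, 3]})
        res = internal_consistency_odd_even(table, "ACQ", "CSP", "T0")
        assert res.r == pytest.approx(0.6)
        assert res.ci_low < 0.6 < res.ci_high

    def test_perfect_split_half_agreement(self):
        table = cs_trials({"P1": [1, 1], "P2": [2, 2], "P3": [3, 3]})
        res = internal_consistency_odd_even(table, "ACQ", "CSP", "T0")
        assert res.r == pytest.approx(1.0)

    def test_zero_variance_half_rejected(self):
        table = cs_trials({"P1": [1, 5], "P2": [1, 2], "P3": [1, 3]})
        with pytest.raises(ValueError, match="zero variance"):
            internal_consistency_odd_even(table, "ACQ", "CSP", "T0")

    def test_participant_order_invariance(self):
        rng = np.random.default_rng(5)
        data = {f"P{i}": rng.random(13) for i in range(10)}
        t1 = cs_trials(data)
        t2 = cs_trials(dict(reversed(list(data.items()))))
        r1 = internal_consistency_odd_even(t1, "ACQ", "CSP", "T0").r
        r2 = internal_consistency_odd_even(t2, "ACQ", "CSP", "T0").r
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestSimilarity:
    def test_between_coefficient_count_is_n_minus_1(self):
        rng = np.random.default_rng(0)
        sim = within_between_similarity(rng.normal(size=(71, 13)), rng.normal(size=(71, 13)))
        assert sim.n_between_per_participant == 70
        assert len(sim.participants) == 71

    def test_within_z_from_known_vectors(self):
        t0 = np.array([[1, 2, 4], [0.5, 1, 2], [3, 1, 2]], dtype=float)
        t1 = np.array([[1, 3, 4], [1, 0.4, 2], [2, 2, 1]], dtype=float)
        sim = within_between_similarity(t0, t1)
        assert sim.within_z[0] == pytest.approx(np.arctanh(39 / 42), abs=1e-9)
        assert sim.within_z[0] == pytest.approx(1.648, abs=1e-3)

    def test_identical_vectors_excluded_as_perfect_correlation(self):
        rng = np.random.default_rng(1)
        t0 = rng.normal(size=(5, 10))
        t1 = rng.normal(size=(5, 10))
        t1[2] = t0[2]  # r = 1 for participant 2
        sim = within_between_similarity(t0, t1)
        assert 2 not in sim.participants
        assert ("perfect_correlation" in dict((i, r) for i, r in sim.excluded).values())

    def test_all_zero_vector_excluded(self):
        rng = np.random.default_rng(2)
        t0 = rng.normal(size=(5, 10))
        t1 = rng.normal(size=(5, 10))
        t0[1] = 0.0
        sim = within_between_similarity(t0, t1)
        assert 1 not in sim.participants
        assert sim.n_between_per_participant == 3

    def test_too_few_survivors_is_an_error(self):
        t0 = np.zeros((4, 6))
        t1 = np.zeros((4, 6))
        with pytest.raises(ValueError, match="fewer than 3"):
            within_between_similarity(t0, t1)


class TestCompareSimilarity:
    def test_identical_samples_give_null_result(self):
        z = np.array([0.2, 0.5, 0.1, 0.9])
        res = compare_similarity(z, z.copy())
        assert res.statistic == 0.0 and res.cohens_d == 0.0 and res.p == 1.0

    def test_constant_nonzero_difference_is_degenerate(self):
        z = np.array([0.2, 0.5, 0.1, 0.9])
        with pytest.raises(ValueError, match="degenerate"):
            compare_similarity(z + 1.0, z)

    def test_welch_used_when_variances_differ(self):
        rng = np.random.default_rng(3)
        w = rng.normal(0, 1.0, 40)
        b = rng.normal(0, 0.05, 40)
        res = compare_similarity(w, b)
        assert res.method == "welch"

    def test_paired_t_used_for_similar_variances(self):
        rng = np.random.default_rng(4)
        w = rng.normal(0.3, 0.5, 40)
        b = rng.normal(0.0, 0.5, 40)
        res = compare_similarity(w, b)
        assert res.method == "paired_t"
        assert res.df == 39
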