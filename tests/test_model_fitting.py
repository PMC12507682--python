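"""Objective, global fitting, Monte Carlo uncertainty and effect sizes."""

import numpy as np
import pytest

from lipoflux import (
    FitResult,
    build_model,
    cohens_d,
    fit_global,
    fold_change,
    mc_uncertainty,
    objective,
)
from lipoflux.model_fitting import classify_d
from conftest import make_timecourse


class TestObjective:
    def test_matches_brute_force_on_constant_model(self, pm_er_model):
        # with all rates zero the model solution is x0 = (1, 0) at all times,
        # so the weighted SSR can be tallied by hand
        tc = make_timecourse([
            (0.0, "PM", 1.0, 0.1, 5), (0.0, "ER", 0.0, 0.1, 5),
            (30.0, "PM", 0.8, 0.1, 5), (30.0, "ER", 0.2, 0.2, 5),
        ])
        params = {"k_PM_ER": 0.0, "k_ER_PM": 0.0}
        expected = ((0.8 - 1.0) / 0.1) ** 2 + ((0.2 - 0.0) / 0.2) ** 2
        assert objective(pm_er_model, params, tc, x0={"PM": 1.0}) == pytest.approx(expected)

    def test_perfect_fit_scores_zero(self, pm_er_model, noiseless_pm_er_tc, pm_er_truth):
        val = objective(pm_er_model, pm_er_truth.rate_params, noiseless_pm_er_tc,
                        x0=pm_er_truth.initial_state)
        assert val == pytest.approx(0.0, abs=1e-10)

    def test_doubling_sd_quarters_ssr(self, pm_er_model):
        rows = [(0.0, "PM", 1.0, 0.1, 5), (0.0, "ER", 0.0, 0.1, 5),
                (30.0, "PM", 0.7, 0.1, 5), (30.0, "ER", 0.3, 0.1, 5)]
        tc1 = make_timecourse(rows)
        tc2 = make_timecourse([(t, o, m, 2 * s, n) for t, o, m, s, n in rows])
        params = {"k_PM_ER": 0.05, "k_ER_PM": 0.02}
        assert objective(pm_er_model, params, tc2, x0={"PM": 1.0}) == pytest.approx(
            objective(pm_er_model, params, tc1, x0={"PM": 1.0}) / 4
        )

    def test_row_order_and_case_invariance(self, pm_er_model):
        rows = [(0.0, "PM", 1.0, 0.1, 5), (0.0, "ER", 0.0, 0.1, 5),
                (30.0, "PM", 0.7, 0.1, 5), (30.0, "ER", 0.3, 0.1, 5)]
        shuffled = [rows[2], rows[0], rows[3], rows[1]]
        lowercase = [(t, o.lower(), m, s, n) for t, o, m, s, n in rows]
        params = {"k_PM_ER": 0.05, "k_ER_PM": 0.02}
        vals = [objective(pm_er_model, params, make_timecourse(r), x0={"PM": 1.0})
                for r in (rows, shuffled, lowercase)]
        assert vals[0] == vals[1] == vals[2]

    def test_extraneous_organelles_excluded(self, pm_er_model):
        tc = make_timecourse([
            (0.0, "PM", 1.0, 0.1, 5), (0.0, "ER", 0.0, 0.1, 5), (0.0, "Golgi", 0.5, 0.1, 5),
            (30.0, "PM", 0.7, 0.1, 5), (30.0, "ER", 0.3, 0.1, 5), (30.0, "Golgi", 0.5, 0.1, 5),
        ])
        params = {"k_PM_ER": 0.0, "k_ER_PM": 0.0}
        expected = ((0.7 - 1.0) / 0.1) ** 2 + ((0.3 - 0.0) / 0.1) ** 2
        assert objective(pm_er_model, params, tc, x0={"PM": 1.0}) == pytest.approx(expected)

    def test_no_shared_organelles_raises(self, pm_er_model):
        tc = make_timecourse([(0.0, "Golgi", 1.0, 0.1, 5), (30.0, "Golgi", 0.5, 0.1, 5)])
        with pytest.raises(ValueError, match="overlap"):
            objective(pm_er_model, {"k_PM_ER": 0.1, "k_ER_PM": 0.1}, tc, x0={"PM": 1.0})


class TestFitGlobal:
    def test_recovers_noiseless_pm_er_within_one_percent(
        self, pm_er_model, noiseless_pm_er_tc, pm_er_truth
    ):
        est, obj_val = fit_global(pm_er_model, noiseless_pm_er_tc, n_starts=5, seed=0,
                                  x0=pm_er_truth.initial_state)
        for name, truth in pm_er_truth.rate_params.items():
            assert est[name] == pytest.approx(truth, rel=0.01)
        assert obj_val < 1e-10

    def test_row_permutation_gives_identical_estimates(self, pm_er_model, noisy_pm_er_tc):
        from lipoflux import TimeCourse

        permuted = TimeCourse(noisy_pm_er_tc.frame.sample(frac=1, random_state=5))
        est1, _ = fit_global(pm_er_model, noisy_pm_er_tc, n_starts=3, seed=7, x0={"PM": 1.0})
        est2, _ = fit_global(pm_er_model, permuted, n_starts=3, seed=7, x0={"PM": 1.0})
        assert est1 == est2

    def test_seed_determinism(self, pm_er_model, noisy_pm_er_tc):
        est1, _ = fit_global(pm_er_model, noisy_pm_er_tc, n_starts=4, seed=3)
        est2, _ = fit_global(pm_er_model, noisy_pm_er_tc, n_starts=4, seed=3)
        assert est1 == est2

    def test_invalid_n_starts(self, pm_er_model, noisy_pm_er_tc):
        with pytest.raises(ValueError):
            fit_global(pm_er_model, noisy_pm_er_tc, n_starts=0)


class TestMcUncertainty:
    def test_zero_sd_data_gives_zero_spread(self, pm_er_model, noiseless_pm_er_tc, pm_er_truth):
        fit = mc_uncertainty(pm_er_model, noiseless_pm_er_tc, n_mc=5, seed=1,
                             n_starts=3, x0=pm_er_truth.initial_state)
        for name in pm_er_model.rate_names:
            assert fit.summary[name][1] == pytest.approx(0.0, abs=1e-6)

    def test_same_seed_identical_samples(self, pm_er_model, noisy_pm_er_tc):
        f1 = mc_uncertainty(pm_er_model, noisy_pm_er_tc, n_mc=6, seed=9, n_starts=3, x0={"PM": 1.0})
        f2 = mc_uncertainty(pm_er_model, noisy_pm_er_tc, n_mc=6, seed=9, n_starts=3, x0={"PM": 1.0})
        for name in pm_er_model.rate_names:
            assert np.array_equal(f1.mc_samples[name], f2.mc_samples[name])

    def test_summary_recomputable_from_samples(self, pm_er_model, noisy_pm_er_tc):
        fit = mc_uncertainty(pm_er_model, noisy_pm_er_tc, n_mc=8, seed=2, n_starts=3, x0={"PM": 1.0})
        for name, (mean, sd) in fit.summary.items():
            assert mean == pytest.approx(np.mean(fit.mc_samples[name]))
            assert sd == pytest.approx(np.std(fit.mc_samples[name], ddof=1))

    def test_truth_within_three_sd(self, pm_er_model, noisy_pm_er_tc, pm_er_truth):
        fit = mc_uncertainty(pm_er_model, noisy_pm_er_tc, n_mc=30, seed=4, n_starts=5,
                             x0=pm_er_truth.initial_state)
        for name, truth in pm_er_truth.rate_params.items():
            mean, sd = fit.summary[name]
            assert abs(mean - truth) <= 3 * sd

    def test_n_mc_floor(self, pm_er_model, noisy_pm_er_tc):
        with pytest.raises(ValueError):
            mc_uncertainty(pm_er_model, noisy_pm_er_tc, n_mc=1)

    def test_round_trip_serialization(self, pm_er_model, noisy_pm_er_tc):
        fit = mc_uncertainty(pm_er_model, noisy_pm_er_tc, n_mc=4, seed=0, n_starts=2, x0={"PM": 1.0})
        restored = FitResult.from_dict(fit.to_dict())
        assert restored.point_estimate == fit.point_estimate
        assert restored.summary == fit.summary

    def test_identifiability_flags_high_cv(self):
        fit = FitResult(point_estimate={},
                        mc_samples={"k_tight": np.array([1.0, 1.01, 0.99, 1.0]),
                                    "k_loose": np.array([0.1, 1.5, 0.01, 2.0])})
        fit.recompute_summary()
        flags = fit.identifiability_flags()
        assert not flags["k_tight"] and flags["k_loose"]


class TestEffectSizes:
    def test_hand_computed_three_element_samples(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 9.0]
        # pooled s^2 = ((2)(1) + (2)(7)) / 4 = 4; d = |2 - 6| / 2 = 2
        eff = cohens_d(a, b)
        assert eff.d == pytest.approx(2.0)
        assert eff.category == "very large"  # d = 2.00 is not strictly > 2.00

    def test_symmetry(self, rng):
        a, b = rng.normal(0, 1, 50), rng.normal(0.5, 2, 60)
        assert cohens_d(a, b).d == pytest.approx(cohens_d(b, a).d)

    def test_identical_samples_negligible(self):
        eff = cohens_d([2.0, 2.1, 1.9], [2.0, 2.1, 1.9])
        assert eff.d == pytest.approx(0.0) and eff.category == "negligible"

    def test_zero_pooled_sd_unequal_means(self):
        eff = cohens_d([1.0, 1.0], [2.0, 2.0])
        assert eff.infinite and eff.category == "huge"

    @pytest.mark.parametrize(
        "d, category",
        [(0.005, "negligible"), (0.01, "negligible"), (0.1, "very small"),
         (0.27, "small"), (0.6, "medium"), (1.0, "large"), (1.5, "very large"),
         (2.3, "huge")],
    )
    def test_category_thresholds(self, d, category):
        assert classify_d(d) == category

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            cohens_d([1.0], [1.0, 2.0])


from hypothesis import given, settings
from hypothesis import strategies as st


@given(shift=st.floats(-10, 10), scale=st.floats(0.01, 100),
       seed=st.integers(0, 2**16))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_cohens_d_shift_and_scale_invariance(shift, scale, seed):
    """d is invariant under common affine transforms of both samples."""
    r = np.random.default_rng(seed)
    a, b = r.normal(0, 1, 8), r.normal(1, 2, 9)
    base = cohens_d(a, b).d
    transformed = cohens_d(scale * a + shift, scale * b + shift).d
    assert transformed == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestFoldChange:
    @staticmethod
    def _fit(mean, sd, name="k_PM_ER"):
        return FitResult(point_estimate={name: mean}, summary={name: (mean, sd)})

    def test_identical_fits_give_unity(self):
        f = self._fit(0.2, 0.02)
        ratio, _ = fold_change(f, f, "k_PM_ER")
        assert ratio == pytest.approx(1.0)

    def test_cptp_ko_style_reduction(self):
        ko, wt = self._fit(0.57 * 0.1, 0.005), self._fit(0.1, 0.005)
        ratio, _ = fold_change(ko, wt, "k_PM_ER")
        assert ratio == pytest.approx(0.57)

    def test_propagated_sd_matches_sampling_within_ten_percent(self, rng):
        # CV < 0.2 on both rates: first-order propagation vs direct MC ratio
        ma, sa, mb, sb = 0.2, 0.02, 0.1, 0.015
        ratio, sd = fold_change(self._fit(ma, sa), self._fit(mb, sb), "k_PM_ER")
        sampled = rng.normal(ma, sa, 100_000) / rng.normal(mb, sb, 100_000)
        assert ratio == pytest.approx(sampled.mean(), rel=0.1)
        assert sd == pytest.approx(sampled.std(), rel=0.1)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            fold_change(self._fit(0.2, 0.01), self._fit(0.0, 0.01), "k_PM_ER")

    def test_missing_rate_rejected(self):
        with pytest.raises(KeyError):
            fold_change(self._fit(0.2, 0.01), self._fit(0.1, 0.01, name="k_other"), "k_PM_ER")
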