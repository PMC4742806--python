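"""Threshold detection: class-averaged partial effects, Davies test,
segmented regression, rates of change and percent reductions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from reefocc.thresholds import (
    davies_test,
    fit_segmented,
    mean_partial_effect,
    percent_reduction,
    rate_of_change,
    threshold_table,
)

X01 = np.linspace(0.0, 1.0, 100)


def _curve_frame(species_curves: dict[str, np.ndarray], correlate="human_impact",
                 x=X01) -> pd.DataFrame:
    from scipy.special import logit
    parts = []
    for sid, prob in species_curves.items():
        prob = np.clip(prob, 1e-6, 1 - 1e-6)
        parts.append(pd.DataFrame({
            "species_id": sid, "correlate": correlate, "x": x,
            "logit": logit(prob), "prob": prob}))
    return pd.concat(parts, ignore_index=True)


def _traits_for(species, body_size=80.0):
    n = len(species)
    return pd.DataFrame({
        "species_id": species,
        "family": ["FamA", "FamB"] * (n // 2) + ["FamA"] * (n % 2),
        "genus": [f"g{i % 4}" for i in range(n)],
        "body_size": body_size,
        "range_size": np.linspace(40, 130, n),
    })


class TestMeanPartialEffect:
    def test_identical_curves_zero_width_ci(self):
        prob = 0.2 + 0.5 * X01
        curves = _curve_frame({f"S{i}": prob for i in range(5)})
        traits = _traits_for([f"S{i}" for i in range(5)])
        eff = mean_partial_effect(curves, traits, ">50", "human_impact",
                                  ci="normal")
        assert np.allclose(eff.mean, prob)
        assert np.allclose(eff.ci_upper - eff.ci_lower, 0.0, atol=1e-12)

    def test_opposite_slopes_average_flat(self):
        curves = _curve_frame({"S0": 0.5 + 0.3 * (X01 - 0.5),
                               "S1": 0.5 - 0.3 * (X01 - 0.5)})
        traits = _traits_for(["S0", "S1"])
        eff = mean_partial_effect(curves, traits, ">50", "human_impact",
                                  ci="normal")
        assert np.ptp(eff.mean) < 1e-12

    def test_empty_group_explicit(self):
        curves = _curve_frame({"S0": 0.5 + 0.0 * X01})
        traits = _traits_for(["S0"], body_size=10.0)  # no species in >50
        eff = mean_partial_effect(curves, traits, ">50", "human_impact")
        assert eff.empty and eff.n_species == 0

    def test_ci_lower_below_mean_below_upper(self, rng):
        curves = _curve_frame({f"S{i}": np.clip(
            0.5 - 0.3 * X01 + 0.05 * rng.standard_normal(100), 0.01, 0.99)
            for i in range(12)})
        traits = _traits_for([f"S{i}" for i in range(12)])
        eff = mean_partial_effect(curves, traits, ">50", "human_impact",
                                  seed=4)
        assert np.all(eff.ci_lower <= eff.mean + 1e-12)
        assert np.all(eff.mean <= eff.ci_upper + 1e-12)
        assert eff.ci_method == "bootstrap"  # < 30 species

    def test_normal_ci_covers_true_mean(self, rng):
        """~95% pointwise coverage over ensembles with Gaussian species
        effects."""
        true = 0.5 - 0.2 * X01
        hits = total = 0
        for rep in range(100):
            curves = _curve_frame({
                f"S{i}": true + 0.08 * rng.standard_normal()  # species offset
                for i in range(40)})
            traits = _traits_for([f"S{i}" for i in range(40)])
            eff = mean_partial_effect(curves, traits, ">50", "human_impact",
                                      ci="normal")
            mid = len(eff.x) // 2
            hits += (eff.ci_lower[mid] <= true[mid] <= eff.ci_upper[mid])
            total += 1
        assert 0.88 <= hits / total <= 0.99

    def test_small_ranging_truncated_at_98th_percentile(self, rng):
        curves = _curve_frame({f"S{i}": 0.5 + 0.0 * X01 for i in range(8)})
        traits = _traits_for([f"S{i}" for i in range(8)])
        eff_all = mean_partial_effect(curves, traits, ">50", "human_impact")
        eff_sr = mean_partial_effect(curves, traits, ">50", "human_impact",
                                     small_ranging=True)
        assert eff_sr.n_species < eff_all.n_species
        assert eff_sr.x.max() <= np.percentile(X01, 98.0) + 1e-12


class TestDaviesTest:
    def test_constant_series_returns_one(self):
        assert davies_test(X01, np.full(100, 0.3)) == 1.0

    def test_type_one_error_conservative(self, rng):
        rej = 0
        n = 200
        for _ in range(n):
            y = 0.2 + 0.9 * X01 + 0.1 * rng.standard_normal(100)
            rej += davies_test(X01, y) < 0.05
        assert rej / n <= 0.08

    def test_power_against_clear_break(self, rng):
        hits = 0
        n = 100
        for _ in range(n):
            y = -2.0 * np.minimum(X01 - 0.5, 0) + 0.1 * rng.standard_normal(100)
            hits += davies_test(X01, y) < 0.05
        assert hits / n >= 0.95

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            davies_test(np.arange(5.0), np.arange(5.0))

    @settings(max_examples=20, deadline=None)
    @given(st.floats(-5, 5), st.floats(0.1, 20), st.floats(-3, 3),
           st.floats(0.2, 10))
    def test_invariant_to_affine_rescaling(self, ax, bx, ay, by):
        rng = np.random.default_rng(17)
        y = np.where(X01 < 0.4, 0.8 - X01, 0.4) + 0.05 * rng.standard_normal(100)
        p1 = davies_test(X01, y)
        p2 = davies_test(ax + bx * X01, ay + by * y)
        assert p1 == pytest.approx(p2, rel=1e-6)


class TestFitSegmented:
    def test_noiseless_break_recovered_exactly(self):
        y = np.where(X01 < 0.5, -2.0 * (X01 - 0.5), 0.0)
        fit = fit_segmented(X01, y, psi0=0.3)
        assert fit.converged
        assert fit.psi == pytest.approx(0.5, abs=1e-6)
        assert fit.slope_before == pytest.approx(-2.0, abs=1e-9)
        assert fit.slope_after == pytest.approx(0.0, abs=1e-9)

    def test_noisy_break_recovered_on_average(self, rng):
        errs = []
        for _ in range(50):
            y = -2.0 * np.minimum(X01 - 0.5, 0) + 0.1 * rng.standard_normal(100)
            fit = fit_segmented(X01, y)
            errs.append(abs(fit.psi - 0.5))
        assert np.mean(errs) < 0.05

    def test_degenerate_no_break_surfaces_uncertainty(self, rng):
        outcomes = []
        for i in range(20):
            y = 0.3 + 0.5 * X01 + 0.1 * rng.standard_normal(100)
            fit = fit_segmented(X01, y)
            outcomes.append((not fit.converged) or fit.psi_se > 0.5)
        assert np.mean(outcomes) >= 0.5

    def test_self_consistency_within_two_se(self, rng):
        """Refitting data simulated from a fitted model re-recovers psi."""
        y = -1.5 * np.minimum(X01 - 0.45, 0) + 0.08 * rng.standard_normal(100)
        base = fit_segmented(X01, y)
        sigma = 0.08
        hits = 0
        for _ in range(20):
            sim = (base.slope_before * np.minimum(X01 - base.psi, 0)
                   + base.slope_after * np.maximum(X01 - base.psi, 0)
                   + sigma * rng.standard_normal(100))
            refit = fit_segmented(X01, sim)
            se = max(refit.psi_se, 1e-6)
            hits += abs(refit.psi - base.psi) <= 2 * se + 1e-9
        assert hits >= 15

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError):
            fit_segmented(np.ones(20), np.arange(20.0), psi0=1.0)


class TestRates:
    def test_rescaled_slope_arithmetic(self):
        x = np.linspace(0, 500, 100)
        y = np.where(x < 250, 0.002 * x, 0.5)
        fit = fit_segmented(x, y, psi0=200)
        before, after = rate_of_change(fit, (0.0, 500.0))
        assert before == pytest.approx(1.0, abs=1e-9)
        assert after == pytest.approx(0.0, abs=1e-9)

    def test_zero_width_range_rejected(self):
        y = np.where(X01 < 0.5, -2.0 * (X01 - 0.5), 0.0)
        fit = fit_segmented(X01, y, psi0=0.4)
        with pytest.raises(ValueError):
            rate_of_change(fit, (1.0, 1.0))

    def test_percent_reduction_worked_examples(self):
        assert percent_reduction(0.7, 0.28) == pytest.approx(60.0)
        assert round(percent_reduction(0.7, 0.231)) == 67
        assert percent_reduction(0.7, 0.7) == 0.0

    def test_percent_reduction_argument_errors(self):
        with pytest.raises(ValueError):
            percent_reduction(0.0, 0.0)
        with pytest.raises(ValueError, match="argument order"):
            percent_reduction(0.3, 0.5)


class TestThresholdTable:
    def _effects(self, rng, plant=True):
        effects = []
        for group, psi in (("<=15", 0.7), (">50", 0.3)):
            if plant:
                base = np.clip(0.7 + 1.2 * np.minimum(X01 - psi, 0), 0.05, 0.95)
            else:
                base = 0.5 - 0.1 * X01
            curves = _curve_frame({
                f"{group}S{i}": np.clip(base + 0.03 * rng.standard_normal(), 0.01, 0.99)
                for i in range(15)})
            traits = _traits_for(list(curves["species_id"].unique()),
                                 body_size=10.0 if group == "<=15" else 80.0)
            effects.append(mean_partial_effect(curves, traits, group,
                                               "human_impact", seed=1))
        return effects

    def test_planted_thresholds_recovered(self, rng):
        table = threshold_table(self._effects(rng, plant=True))
        assert (table["davies_p"] < 0.05).all()
        for _, row in table.iterrows():
            truth = 0.7 if row["group"] == "<=15" else 0.3
            assert abs(row["threshold"] - truth) <= max(2 * row["threshold_se"], 0.05)

    def test_large_fish_threshold_precedes_small_fish(self, rng):
        table = threshold_table(self._effects(rng, plant=True)).set_index("group")
        assert table.loc[">50", "threshold"] < table.loc["<=15", "threshold"]

    def test_no_break_rows_carry_na(self, rng):
        table = threshold_table(self._effects(rng, plant=False))
        assert table["threshold"].isna().all()

    def test_end_to_end_large_fish_effect_non_increasing(self, brt_results,
                                                         traits):
        """Default scenario, fully through the BRT stage: the mean
        human-impact partial effect of the >50 cm class declines."""
        from sklearn.isotonic import IsotonicRegression
        import reefocc.brt as brt_mod
        curves = brt_mod.curves_to_frame([r for r in brt_results if r.converged])
        eff = mean_partial_effect(curves, traits, ">50", "human_impact", seed=1)
        assert eff.n_species >= 2
        iso = IsotonicRegression(increasing=False).fit_transform(eff.x, eff.mean)
        assert np.abs(eff.mean - iso).max() < 0.05
        assert eff.mean[0] - eff.mean[-1] > 0.05  # a real decline, not flat

    def test_schema_stable(self, rng):
        t1 = threshold_table(self._effects(rng, plant=True))
        t2 = threshold_table(self._effects(rng, plant=False))
        assert list(t1.columns) == list(t2.columns)
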