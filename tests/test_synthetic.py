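"""Synthetic-data generator: covariate structure, traits, occurrence,
surveys and missingness."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import reefocc
from reefocc.ranges import convex_hull_eoo
from reefocc.synthetic import (
    CORRELATE_COLUMNS,
    ConfigurationError,
    PiecewiseEffect,
    TrueModelParams,
    apply_missingness,
    make_restricted_lists,
    pooled_presence,
    size_class,
    small_ranging_flag,
)


class TestGenerateLocations:
    def test_empty_table_keeps_schema(self):
        df = reefocc.generate_locations(0, seed=1)
        assert len(df) == 0
        assert list(df.columns) == ["location_id", "lon", "lat", *CORRELATE_COLUMNS]

    def test_deterministic_given_seed(self):
        a = reefocc.generate_locations(50, seed=7)
        b = reefocc.generate_locations(50, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_pairwise_correlations_below_ceiling(self):
        df = reefocc.generate_locations(500, seed=3)
        corr = df[CORRELATE_COLUMNS].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() < 0.7

    def test_no_missing_and_physical_bounds(self):
        df = reefocc.generate_locations(200, seed=5)
        assert not df.isna().any().any()
        for c in ["dist_to_land", "reef_area", "reef_area_50km", "dist_to_IAA"]:
            assert (df[c] >= 0).all()
        assert df["rel_margin_dist"].between(0, 1).all()

    def test_non_psd_target_is_configuration_error(self):
        k = len(CORRELATE_COLUMNS) - 1  # dist_to_IAA is derived, not copula
        bad = np.full((k, k), 0.99)
        np.fill_diagonal(bad, 1.0)
        bad[0, 1] = bad[1, 0] = -0.99  # inconsistent -> negative eigenvalue
        with pytest.raises(ConfigurationError):
            reefocc.generate_locations(10, seed=1, corr=bad)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            reefocc.generate_locations(-1)


class TestGenerateSpecies:
    def test_size_class_boundaries(self):
        assert size_class(60) == ">50"
        assert size_class(15) == "<=15"
        assert size_class(16) == "16-50"
        assert size_class(50) == "16-50"

    def test_small_ranging_is_first_quartile(self):
        tr = reefocc.generate_species(200, seed=2)
        flag = small_ranging_flag(tr, within_class=False)
        q1 = tr["range_size"].quantile(0.25)
        assert ((tr["range_size"] <= q1) == flag).all()

    def test_small_ranging_within_class_quartile(self):
        tr = reefocc.generate_species(200, seed=2)
        flag = small_ranging_flag(tr, within_class=True)
        cls = pd.Series(size_class(tr["body_size"]), index=tr.index)
        for c in np.unique(cls):
            sub = tr[cls == c]
            assert flag[sub.index].sum() == (sub["range_size"]
                                             <= sub["range_size"].quantile(0.25)).sum()

    def test_size_range_coupling_positive(self):
        tr = reefocc.generate_species(1000, seed=4, coupling=True)
        rho = spearmanr(tr["body_size"], tr["range_size"]).statistic
        assert rho > 0.2

    def test_coupling_off_uncorrelated(self):
        tr = reefocc.generate_species(1000, seed=4, coupling=False)
        rho = spearmanr(tr["body_size"], tr["range_size"]).statistic
        assert abs(rho) < 0.1

    def test_taxonomy_and_invariants(self):
        tr = reefocc.generate_species(100, seed=6)
        assert (tr["body_size"] > 3).all()
        assert (tr["range_size"] > 0).all()
        assert tr["genus"].notna().all() and tr["family"].notna().all()
        # genera nest within families: one family per genus label
        assert (tr.groupby("genus")["family"].nunique() == 1).all()


def _uniform_correlates(n, human_impact=None):
    """Constant correlate table except an optional human-impact gradient."""
    df = reefocc.generate_locations(n, seed=9)
    for c in CORRELATE_COLUMNS:
        df[c] = df[c].mean()
    if human_impact is not None:
        df["human_impact"] = human_impact
    return df


def _free_params(**kw):
    return TrueModelParams(
        intercept=kw.pop("intercept", 0.0),
        linear_slopes=kw.pop("linear_slopes", {}),
        piecewise=kw.pop("piecewise", {}),
        size_scaling={}, range_scaling={}, **kw)


class TestSimulateOccurrence:
    def test_null_params_give_half_probability(self, traits):
        correlates = _uniform_correlates(30)
        sim = reefocc.simulate_occurrence(traits.head(5), correlates,
                                          _free_params(), hulls=None, seed=1)
        assert np.allclose(sim.prob.to_numpy(), 0.5)

    def test_probability_monotone_in_human_impact(self, traits):
        hi = np.linspace(2, 60, 40)
        correlates = _uniform_correlates(40, human_impact=hi)
        params = _free_params(piecewise={
            "human_impact": PiecewiseEffect(threshold=12.0, slope_before=0.0,
                                            slope_after=-1.5)})
        sim = reefocc.simulate_occurrence(traits.head(3), correlates, None or params,
                                          hulls=None, seed=1)
        p = sim.prob.iloc[:, 0].to_numpy()
        assert np.all(np.diff(p) <= 1e-12)

    def test_bernoulli_frequency_matches_probability(self, traits):
        # 10,000 iid cells with true p = 0.3
        p_target = 0.3
        correlates = _uniform_correlates(10_000)
        params = _free_params(intercept=float(np.log(p_target / (1 - p_target))))
        sim = reefocc.simulate_occurrence(traits.head(1), correlates, params,
                                          hulls=None, seed=21)
        freq = sim.matrix.iloc[:, 0].mean()
        se = np.sqrt(p_target * (1 - p_target) / 10_000)
        assert abs(freq - p_target) < 3 * se

    def test_out_of_range_cells_absent(self, occurrence):
        m = occurrence.matrix.to_numpy()
        inr = occurrence.in_range.to_numpy()
        assert m[~inr].sum() == 0
        assert (occurrence.prob.to_numpy()[~inr] == 0).all()

    def test_disjoint_hull_warns_and_all_absent(self, traits):
        correlates = _uniform_correlates(10)
        far = convex_hull_eoo(np.array([[300.0, 80.0], [301, 80], [300.5, 81]]),
                              species_id="SP000")
        t1 = traits.head(1)
        with pytest.warns(UserWarning, match="overlaps no survey location"):
            sim = reefocc.simulate_occurrence(t1, correlates, _free_params(),
                                              hulls={"SP000": far}, seed=1)
        assert sim.matrix.to_numpy().sum() == 0


class TestSimulateSurveys:
    def test_certain_detection_records_every_occupied_cell(self, occurrence, traits):
        params = _free_params(detect_intercept=30.0, detect_size_slope=0.0,
                              detect_offsets={}, avoidance_base=0.0)
        sv = reefocc.simulate_surveys(occurrence, traits, params,
                                      n_replicates=2, seed=3)
        pooled = pooled_presence(sv)
        pd.testing.assert_frame_equal(
            pooled.astype(float), occurrence.matrix.astype(float),
            check_dtype=False)

    def test_absent_species_never_detected(self, occurrence, traits, survey):
        det = survey.dropna(subset=["detected"])
        pooled = det.groupby(["location_id", "species_id"])["detected"].max()
        m = occurrence.matrix.stack()
        absent = m[m == 0]
        joined = pooled.reindex(absent.index).dropna()
        assert (joined == 0).all()

    def test_detection_rate_matches_probability(self, traits):
        # ~5,000 occupied cells with per-replicate detection p = 0.25
        p_det = 0.25
        correlates = _uniform_correlates(5000)
        occ = reefocc.simulate_occurrence(traits.head(1), correlates,
                                          _free_params(intercept=50.0),
                                          hulls=None, seed=5)
        params = _free_params(
            detect_intercept=float(np.log(p_det / (1 - p_det))),
            detect_size_slope=0.0, detect_offsets={}, detect_area_coef=0.0)
        sv = reefocc.simulate_surveys(occ, traits.head(1), params,
                                      n_replicates=1, seed=6)
        frac = sv["detected"].astype(float).mean()
        se = np.sqrt(p_det * (1 - p_det) / 5000)
        assert abs(frac - p_det) < 4 * se

    def test_replicates_conditionally_independent(self, traits):
        # detections of replicate pairs at occupied cells are independent
        correlates = _uniform_correlates(4000)
        occ = reefocc.simulate_occurrence(traits.head(1), correlates,
                                          _free_params(intercept=50.0),
                                          hulls=None, seed=5)
        params = _free_params(detect_intercept=0.0, detect_size_slope=0.0,
                              detect_offsets={}, detect_area_coef=0.0)
        sv = reefocc.simulate_surveys(occ, traits.head(1), params,
                                      n_replicates=2, seed=8)
        piv = sv.pivot_table(index="location_id", columns="replicate_id",
                             values="detected").to_numpy()
        from scipy.stats import chi2_contingency
        table = np.array([[np.sum((piv[:, 0] == a) & (piv[:, 1] == b))
                           for b in (0, 1)] for a in (0, 1)])
        assert chi2_contingency(table).pvalue > 0.001

    def test_positive_replicate_count_required(self, occurrence, traits, params):
        with pytest.raises(ValueError):
            reefocc.simulate_surveys(occurrence, traits, params, n_replicates=0)


class TestMissingness:
    def test_empty_lists_identity(self, survey):
        out = apply_missingness(survey.copy(), {})
        assert out.attrs["na_fraction"] == 0.0
        pd.testing.assert_frame_equal(out, survey, check_dtype=False)

    def test_full_source_restriction_blanks_everything(self, survey, traits):
        src = survey["data_source"].iloc[0]
        out = apply_missingness(survey.copy(),
                                {src: list(traits["species_id"])})
        sub = out[out["data_source"] == src]
        assert sub["detected"].isna().all()

    def test_unknown_species_or_source_rejected(self, survey):
        with pytest.raises(ValueError, match="unknown data source"):
            apply_missingness(survey, {"NOPE": []})
        src = survey["data_source"].iloc[0]
        with pytest.raises(ValueError, match="unknown species"):
            apply_missingness(survey, {src: ["SPX999"]})

    def test_calibrated_na_fraction_near_eight_percent(self, occurrence, traits,
                                                       params, correlates):
        sv = reefocc.simulate_surveys(occurrence, traits, params,
                                      n_replicates=4, seed=31, correlates=correlates)
        lists = make_restricted_lists(sv, traits, target_fraction=0.08, seed=31)
        out = apply_missingness(sv, lists)
        assert out.attrs["na_fraction"] == pytest.approx(0.08, abs=0.01)

    def test_na_is_missing_not_absent(self, survey):
        # pooled matrix keeps NA where every record is blanked
        pooled = pooled_presence(survey)
        assert pooled.isna().to_numpy().sum() > 0


class TestDeterminism:
    def test_full_chain_bit_identical(self, correlates):
        out = []
        for _ in range(2):
            tr = reefocc.generate_species(10, seed=13)
            h = reefocc.generate_ranges(tr, correlates, seed=13)
            occ = reefocc.simulate_occurrence(tr, correlates,
                                              reefocc.default_params(), h, seed=13)
            sv = reefocc.simulate_surveys(occ, tr, reefocc.default_params(),
                                          n_replicates=3, seed=13)
            out.append((tr, occ.matrix, sv))
        pd.testing.assert_frame_equal(out[0][0], out[1][0])
        pd.testing.assert_frame_equal(out[0][1], out[1][1])
        pd.testing.assert_frame_equal(out[0][2], out[1][2])
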