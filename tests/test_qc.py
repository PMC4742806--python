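"""Quality-control layer: detectability proxy and models, false absences,
PERMANOVA, missingness PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import reefocc
import reefocc.qc as qc
from reefocc.glmm import fit_binomial_glmm
from reefocc.qc import (
    detection_proportion,
    false_absence_rate,
    false_absence_trend_test,
    fit_detectability_model,
    missingness_pca_check,
    permanova,
)


def _mini_survey(detections, n_replicates=4, species="SP001", location="L0001"):
    """One (species, location) cell with the given per-replicate detections."""
    return pd.DataFrame({
        "location_id": location,
        "replicate_id": [f"R{i+1}" for i in range(n_replicates)],
        "transect_area": 250.0,
        "data_source": "RLS",
        "species_id": species,
        "detected": pd.array(detections, dtype="Float64"),
        "distance_band": [("within-5m" if d == 1 else None) for d in detections],
        "fishing_intensity": 2,
    })


class TestDetectionProportion:
    def test_one_of_four_replicates(self):
        rec = detection_proportion(_mini_survey([1, 0, 0, 0]))
        assert len(rec) == 1
        assert rec["P"].iloc[0] == pytest.approx(0.25)

    def test_four_of_four_replicates(self):
        rec = detection_proportion(_mini_survey([1, 1, 1, 1]))
        assert rec["P"].iloc[0] == pytest.approx(1.0)

    def test_no_detection_no_row(self):
        # presence unknown: conditioning on pooled presence drops the cell
        rec = detection_proportion(_mini_survey([0, 0, 0, 0]))
        assert len(rec) == 0

    def test_na_records_excluded(self):
        sv = _mini_survey([1, 1, 0, 0])
        sv.loc[1, "detected"] = pd.NA
        rec = detection_proportion(sv)
        assert rec["n_replicates"].iloc[0] == 3
        assert rec["P"].iloc[0] == pytest.approx(1 / 3)

    def test_scale_free_under_replicate_duplication(self, survey):
        rec1 = detection_proportion(survey)
        doubled = pd.concat([survey, survey.assign(
            replicate_id=survey["replicate_id"] + "b")], ignore_index=True)
        rec2 = detection_proportion(doubled)
        merged = rec1.merge(rec2, on=["species_id", "location_id"],
                            suffixes=("_1", "_2"))
        assert len(merged) == len(rec1)
        assert np.allclose(merged["P_1"], merged["P_2"])


def _simulate_records(n, seed, size_slope=-0.2, behaviour_effects=False,
                      source_sd=0.3, taxon_sd=0.3, n_reps=4):
    """Detection records drawn from the model1 generating process."""
    rng = np.random.default_rng(seed)
    # keep detection probabilities high enough that conditioning on >=1
    # detection truncates almost nothing (else the slope attenuates)
    body = rng.uniform(5.0, 20.0, n)
    mobility = rng.choice(["low", "high"], n)
    schooling = rng.choice(["Sol", "SmallG"], n)
    water = rng.choice(["bottom", "high"], n)
    family = rng.choice([f"F{i}" for i in range(8)], n)
    genus = np.array([f"{f}_g{rng.integers(2)}" for f in family])
    source = rng.choice(["A", "B", "C"], n)
    b_src = dict(zip("ABC", rng.normal(0, source_sd, 3)))
    fams = {f: rng.normal(0, taxon_sd) for f in np.unique(family)}
    eta = 5.0 + size_slope * body
    if behaviour_effects:
        eta = eta - 0.4 * (mobility == "high") - 0.5 * (schooling == "Sol")
    eta = eta + np.array([b_src[s] for s in source]) + np.array([fams[f] for f in family])
    k = rng.binomial(n_reps, expit(eta))
    keep = k > 0
    return pd.DataFrame({
        "species_id": [f"SP{i:04d}" for i in range(n)],
        "location_id": [f"L{i:04d}" for i in range(n)],
        "detected_count": k, "n_replicates": n_reps, "transect_area": 250.0,
        "data_source": source, "fishing_intensity": 1,
        "P": k / n_reps,
    })[keep], pd.DataFrame({
        "species_id": [f"SP{i:04d}" for i in range(n)],
        "family": family, "genus": genus, "body_size": body,
        "mobility": mobility, "schooling": schooling, "water_level": water,
        "range_size": 50.0,
    })[keep]


class TestDetectabilityGLMM:
    def test_matches_glm_without_random_effects(self, rng):
        n = 300
        x = rng.standard_normal(n)
        trials = rng.integers(2, 6, n)
        k = rng.binomial(trials, expit(0.3 + 0.5 * x))
        X = pd.DataFrame({"intercept": 1.0, "x": x})
        res = fit_binomial_glmm(k, trials, X)
        import statsmodels.api as sm
        glm = sm.GLM(np.column_stack([k, trials - k]), X.to_numpy(),
                     family=sm.families.Binomial()).fit()
        assert np.allclose(res.params, glm.params, atol=1e-5)
        assert res.loglik == pytest.approx(glm.llf, abs=1e-4)
        assert np.allclose(res.bse, glm.bse, atol=1e-4)

    def test_body_size_slope_recovery(self):
        records, traits = _simulate_records(2000, seed=5, size_slope=-0.2)
        fit = fit_detectability_model(records, traits, model="model1")
        est = fit.result.params["body_size"]
        se = fit.result.bse["body_size"]
        assert est - 1.96 * se <= -0.2 <= est + 1.96 * se
        assert fit.result.vc.keys() == {"data_source", "family", "genus"}

    def test_model1_preferred_when_true(self, correlates):
        """When detection depends only on size/behaviour, the geographic
        models should rarely beat model1 on wAICc."""
        wins = 0
        n_rep = 12
        loc_ids = correlates["location_id"].to_numpy()
        for i in range(n_rep):
            records, traits = _simulate_records(400, seed=100 + i,
                                                behaviour_effects=True)
            records = records.assign(
                location_id=np.random.default_rng(i).choice(loc_ids, len(records)))
            table, _ = qc.compare_detectability_models(records, traits, correlates)
            best = table.sort_values("AICc")["model"].iloc[0]
            wins += best == "model1"
        assert wins >= int(0.7 * n_rep)

    def test_null_covariates_give_null_slopes(self):
        records, traits = _simulate_records(800, seed=9, size_slope=0.0,
                                            source_sd=0.0, taxon_sd=0.0)
        fit = fit_detectability_model(records, traits, model="model1")
        ci = fit.result.conf_int()
        assert ci.loc["body_size", "lower"] <= 0.0 <= ci.loc["body_size", "upper"]

    def test_unknown_model_label_rejected(self, survey, traits):
        with pytest.raises(ValueError):
            fit_detectability_model(pd.DataFrame(), traits, model="model9")


class TestFalseAbsences:
    def test_always_within_gives_zero_rates(self):
        sv = _mini_survey([1, 1, 1, 1])
        res = false_absence_rate(sv)
        assert (res.summary["rate"] == 0).all()

    def test_two_of_ten_beyond_only(self):
        parts = []
        for i in range(10):
            s = _mini_survey([1], n_replicates=1, location=f"L{i:04d}")
            if i < 2:
                s["distance_band"] = "beyond-5m"
            parts.append(s)
        res = false_absence_rate(pd.concat(parts, ignore_index=True))
        assert res.by_species["rate"].iloc[0] == pytest.approx(0.2)

    def test_no_band_data_gives_explicit_empty(self):
        sv = _mini_survey([1, 1, 0, 0])
        sv["distance_band"] = None
        res = false_absence_rate(sv)
        assert res.empty
        assert len(res.summary) == 0

    def test_no_fishing_trend_when_avoidance_independent(self, occurrence, traits,
                                                         params, correlates):
        """Avoidance independent of fishing -> trend test mostly
        non-significant."""
        sig = 0
        n_rep = 10
        for i in range(n_rep):
            sv = reefocc.simulate_surveys(occurrence, traits, params,
                                          n_replicates=2, seed=500 + i,
                                          correlates=correlates)
            _, p = false_absence_trend_test(sv, traits, n_perm=99, seed=i)
            sig += p < 0.05
        assert sig <= 2


class TestPermanova:
    def test_separated_groups_hit_minimum_p(self, rng):
        a = rng.normal(0, 0.1, size=(15, 3))
        b = rng.normal(50, 0.1, size=(15, 3))
        pts = np.vstack([a, b])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        f, p = permanova(d, ["a"] * 15 + ["b"] * 15, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)
        assert f > 100

    def test_type_one_error_calibrated(self, rng):
        rej = 0
        trials = 200
        for i in range(trials):
            pts = rng.normal(size=(24, 3))
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            labels = ["a"] * 12 + ["b"] * 12
            _, p = permanova(d, labels, n_perm=199, seed=i)
            rej += p < 0.05
        assert 0.01 <= rej / trials <= 0.10

    def test_single_member_group_named_in_error(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError, match="'b'"):
            permanova(d, ["a", "a", "b"], n_perm=9)

    def test_asymmetric_matrix_rejected(self):
        d = np.arange(9.0).reshape(3, 3)
        with pytest.raises(ValueError):
            permanova(d, ["a", "a", "b"])

    def test_source_effect_on_fixture(self, survey):
        f, p = qc.source_effect_test(survey, n_perm=99, seed=1)
        assert np.isfinite(f) and 0 < p <= 1


class TestMissingnessPCA:
    def test_variance_explained_sums_to_hundred(self, correlates):
        mask = np.zeros(len(correlates), dtype=bool)
        mask[:10] = True
        res = missingness_pca_check(correlates, mask, n_perm=99, seed=0)
        assert res.var_explained.sum() == pytest.approx(100.0)

    def test_uniform_missingness_rarely_flagged(self, correlates, rng):
        flagged = 0
        n_rep = 20
        for i in range(n_rep):
            mask = rng.random(len(correlates)) < 0.1
            if mask.sum() < 2:
                mask[:2] = True
            res = missingness_pca_check(correlates, mask, n_perm=199, seed=i)
            flagged += res.p_value <= 0.05
        assert flagged <= 4

    def test_planted_missingness_detected(self, correlates):
        top = correlates["human_impact"] >= correlates["human_impact"].quantile(0.9)
        res = missingness_pca_check(correlates, top.to_numpy(), n_perm=999, seed=3)
        assert res.p_value <= 0.01

    def test_constant_column_dropped_with_warning(self, correlates):
        df = correlates.copy()
        df["sst_mean"] = 27.0
        mask = np.zeros(len(df), dtype=bool)
        mask[:5] = True
        with pytest.warns(UserWarning, match="constant"):
            res = missingness_pca_check(df, mask, n_perm=49, seed=0)
        assert "sst_mean" in res.dropped_columns
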