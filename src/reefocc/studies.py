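"""Replicated simulation studies over the synthetic pipeline.

These are the package's built-in calibration and validation experiments:
each generates data under known conditions, runs the relevant stage(s),
and reports recovery or error rates.  They back the acceptance checks and
the worked examples, and are sized for a single desk CPU (problem sizes
in docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from . import brt as brt_mod
from . import synthetic as syn
from . import thresholds as thr
from . import traits as traits_mod
from .brt import BRTSettings

__all__ = [
    "detectability_worked_examples",
    "davies_type1_study",
    "breakpoint_recovery_study",
    "generate_study_world",
    "null_model_study",
    "effect_structure_study",
    "DESK_BRT_SETTINGS",
    "NULL_BRT_SETTINGS",
]

#: study conditions: the synthetic stand-in for the survey compilation
N_LOCATIONS = 150
N_SPECIES = 40
N_REPLICATES = 4

#: desk-scale boosting profile for full (signal) runs
DESK_BRT_SETTINGS = BRTSettings(max_trees=500, n_folds=5, seed=0)
#: reduced profile for the heavily replicated null study (tree count and
#: learning rate are irrelevant to the null's expected outcome)
NULL_BRT_SETTINGS = BRTSettings(max_trees=150, n_folds=3, learning_rate=0.05,
                                min_trees_for_convergence=1, seed=0)

TRAIT_CANDIDATES = ("log_body_size", "log_range_size", "trophic_group", "mobility")


def detectability_worked_examples() -> dict[str, float]:
    """The two printed worked examples of the detectability proxy:
    a species sighted on 1/4 replicates (P = 0.25) and on 4/4 (P = 1)."""
    from .qc import detection_proportion

    def survey_with(detections):
        return pd.DataFrame({
            "location_id": "L0001",
            "replicate_id": [f"R{i+1}" for i in range(len(detections))],
            "transect_area": 250.0, "data_source": "RLS",
            "species_id": "SP001",
            "detected": pd.array(detections, dtype="Float64"),
            "distance_band": None, "fishing_intensity": 1,
        })

    p14 = detection_proportion(survey_with([1, 0, 0, 0]))["P"].iloc[0]
    p44 = detection_proportion(survey_with([1, 1, 1, 1]))["P"].iloc[0]
    return {"P_1_of_4": float(p14), "P_4_of_4": float(p44)}


def davies_type1_study(n_sim: int = 1000, n_points: int = 100,
                       alpha: float = 0.05, seed: int = 0) -> dict[str, float]:
    """Type-I error of the Davies test on linear-null data."""
    rng = syn.substream(seed, 20)
    x = np.linspace(0.0, 1.0, n_points)
    rej = 0
    for _ in range(n_sim):
        y = 0.2 + 0.9 * x + 0.1 * rng.standard_normal(n_points)
        rej += thr.davies_test(x, y) < alpha
    return {"rejection_rate": rej / n_sim, "n": n_sim}


def breakpoint_recovery_study(
    n_rep: int = 200,
    n_points: int = 100,
    n_species: int = 25,
    psi_true: float = 0.5,
    slope_change: float = 0.5,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> dict[str, float]:
    """Breakpoint recovery on synthetic mean partial-effect curves.

    Each replicate builds an ensemble of per-species probability curves —
    a piecewise-linear truth with a slope change of ``slope_change``
    (5x ``noise_sd`` at the defaults) at ``psi_true``, plus Gaussian
    species-level noise — averages them with
    :func:`reefocc.thresholds.mean_partial_effect`, runs the Davies test
    and the segmented fit, and scores a success when p < 0.05 and the
    estimated threshold lands within 5% of the x range of the truth.
    """
    rng = syn.substream(seed, 21)
    x = np.linspace(0.0, 1.0, n_points)
    true_curve = 0.65 + slope_change * np.minimum(x - psi_true, 0.0)
    species = [f"S{i:02d}" for i in range(n_species)]
    traits = pd.DataFrame({
        "species_id": species,
        "family": ["FamA", "FamB"] * (n_species // 2) + ["FamA"] * (n_species % 2),
        "genus": [f"g{i % 4}" for i in range(n_species)],
        "body_size": 80.0,
        "range_size": np.linspace(40, 130, n_species),
    })
    hits = 0
    abs_err = []
    for _ in range(n_rep):
        parts = []
        for s in species:
            prob = np.clip(true_curve + noise_sd * rng.standard_normal(n_points),
                           1e-4, 1 - 1e-4)
            parts.append(pd.DataFrame({
                "species_id": s, "correlate": "human_impact", "x": x,
                "logit": np.log(prob / (1 - prob)), "prob": prob}))
        curves = pd.concat(parts, ignore_index=True)
        eff = thr.mean_partial_effect(curves, traits, ">50", "human_impact",
                                      ci="normal")
        p = thr.davies_test(eff.x, eff.mean)
        fit = thr.fit_segmented(eff.x, eff.mean)
        err = abs(fit.psi - psi_true)
        abs_err.append(err)
        hits += (p < 0.05) and (err < 0.05 * np.ptp(x))
    return {"success_rate": hits / n_rep,
            "mean_abs_error": float(np.mean(abs_err)), "n": n_rep}


def generate_study_world(seed: int, n_loc: int = N_LOCATIONS,
                         n_sp: int = N_SPECIES,
                         n_replicates: int = N_REPLICATES):
    """One synthetic survey compilation under the default study conditions."""
    params = syn.default_params()
    correlates = syn.generate_locations(n_loc, seed=seed)
    traits = syn.generate_species(n_sp, seed=seed)
    hulls = syn.generate_ranges(traits, correlates, seed=seed)
    occ = syn.simulate_occurrence(traits, correlates, params, hulls, seed=seed)
    survey = syn.simulate_surveys(occ, traits, params, n_replicates=n_replicates,
                                  seed=seed, correlates=correlates)
    lists = syn.make_restricted_lists(survey, traits, seed=seed)
    survey = syn.apply_missingness(survey, lists)
    matrix = syn.pooled_presence(survey)
    return correlates, traits, hulls, matrix


def null_model_study(
    n_rep: int = 50,
    seed: int = 0,
    n_loc: int = N_LOCATIONS,
    n_sp: int = N_SPECIES,
    settings: BRTSettings = NULL_BRT_SETTINGS,
    candidates: Sequence[str] = TRAIT_CANDIDATES,
) -> dict:
    """Within-range permutation null, replicated.

    Each replicate generates a survey compilation, permutes every species'
    presences within its range (a fresh single randomization), refits the
    BRTs, and builds the five trait-model sets on the null outputs.
    Reported: the distribution of null CV deviance explained and, per
    response, how often the intercept-only model is selected.
    """
    null_best = {r: 0 for r in traits_mod.RESPONSES}
    fitted = {r: 0 for r in traits_mod.RESPONSES}
    cv_values: list[float] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_rep):
            rep_seed = int(syn.substream(seed, 22, i).integers(2**31))
            correlates, traits, hulls, matrix = generate_study_world(
                rep_seed, n_loc=n_loc, n_sp=n_sp)
            s = dataclasses.replace(settings, seed=rep_seed)
            results = brt_mod.run_all_species(matrix, correlates, traits, s,
                                              null=True, hulls=hulls,
                                              curve_correlates=None)
            cv_values.extend(r.cv_deviance_explained for r in results
                             if r.converged)
            hyp = traits_mod.aggregate_contributions(results)
            if len(hyp) < 10:
                continue
            data = traits_mod.make_trait_data(hyp, traits)
            for resp in traits_mod.RESPONSES:
                ms = traits_mod.build_model_set(data, resp, list(candidates))
                fitted[resp] += 1
                null_best[resp] += ms.best_formula == "1"
    cv = np.asarray(cv_values)
    return {
        "n_rep": n_rep,
        "null_cv_deviance_mean": float(cv.mean()),
        "null_cv_deviance_sd": float(cv.std(ddof=1)),
        "null_selection_fraction": {
            r: (null_best[r] / fitted[r] if fitted[r] else np.nan)
            for r in traits_mod.RESPONSES},
        "n_null_fits": int(len(cv)),
    }


def effect_structure_study(
    seed: int = 0,
    n_worlds: int = 3,
    n_loc: int = N_LOCATIONS,
    n_sp: int = N_SPECIES,
    settings: BRTSettings = DESK_BRT_SETTINGS,
    candidates: Sequence[str] = TRAIT_CANDIDATES,
) -> dict:
    """Recovery of the planted trait-dependent effect structure.

    Pools converged species over ``n_worlds`` generator replicates, then
    checks (a) that the mean human-pressure contribution is ordered across
    the three body-size classes, and (b) that the wAICc-model-averaged
    human-pressure surface attains its maximum at the large-body/
    small-range corner of trait space.
    """
    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_worlds):
            rep_seed = int(syn.substream(seed, 23, i).integers(2**31))
            correlates, traits, hulls, matrix = generate_study_world(
                rep_seed, n_loc=n_loc, n_sp=n_sp)
            s = dataclasses.replace(settings, seed=rep_seed)
            results = brt_mod.run_all_species(matrix, correlates, traits, s,
                                              hulls=hulls, curve_correlates=None)
            hyp = traits_mod.aggregate_contributions(results)
            d = traits_mod.make_trait_data(hyp, traits)
            d["species_id"] = d["species_id"] + f"_w{i}"
            frames.append(d)
        data = pd.concat(frames, ignore_index=True)
        data["size_class"] = syn.size_class(data["body_size"])
        class_means = data.groupby("size_class")["human_pressure"].mean()
        ordered = bool(class_means["<=15"] < class_means["16-50"]
                       < class_means[">50"])

        ms = traits_mod.build_model_set(data, "human_pressure", list(candidates))
        n_grid = 20
        grid = traits_mod.prediction_grid(data, n=n_grid)
        surface = traits_mod.model_average(ms, grid).reshape(n_grid, n_grid)
    corners = {
        "small_body_small_range": float(surface[0, 0]),
        "small_body_large_range": float(surface[0, -1]),
        "large_body_small_range": float(surface[-1, 0]),
        "large_body_large_range": float(surface[-1, -1]),
    }
    target = corners["large_body_small_range"]
    corner_ok = target >= max(corners.values()) - 1e-9
    return {
        "class_mean_human_pressure": {k: float(v) for k, v in class_means.items()},
        "ordered": ordered,
        "corners": corners,
        "corner_ok": bool(corner_ok),
        "best_formula": ms.best_formula,
        "n_species_pooled": int(len(data)),
    }
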