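"""Per-species boosted regression trees for presence/absence.

Each species' occurrence over locations is modelled by stochastic gradient
boosting on binomial deviance (logit link) with the standard settings used
for cross-species comparability: tree complexity (interaction depth) 3,
learning rate 0.01, bag fraction 0.5.  The number of trees is the only
tuned quantity: it minimizes the mean out-of-fold binomial deviance over
boosting stages under stratified k-fold cross-validation, and the final
model is refit on all rows at that stage count.

Outputs per species: cross-validated percent deviance explained (relative
to the null binomial deviance), per-correlate relative contributions
(split-gain shares normalized to 100), and partial-dependence curves
(model prediction as a function of one correlate, averaged over the
training rows, on the logit scale).

Tree growing is delegated to LightGBM; stage selection, deviance
accounting, contribution normalization and partial dependence live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

from .ranges import RangeHull, within_range
from .synthetic import CORRELATE_COLUMNS, substream

__all__ = [
    "BRTSettings",
    "BRTResult",
    "StratifiedFoldError",
    "fit_species_brt",
    "relative_contributions",
    "partial_dependence",
    "null_randomize",
    "run_all_species",
    "results_to_frame",
    "curves_to_frame",
    "HEADLINE_CORRELATES",
]

#: the strongest correlate of each hypothesis family; partial-dependence
#: curves are always materialized for these.
HEADLINE_CORRELATES = ("dist_to_land", "reef_area_50km", "sst_sdev", "human_impact")


class StratifiedFoldError(ValueError):
    """Raised when a class has fewer cases than cross-validation folds."""


@dataclass(frozen=True)
class BRTSettings:
    """Boosting hyperparameters.

    Defaults follow the fixed cross-species settings (complexity 3,
    learning rate 0.01, bag fraction 0.5) with 10-fold CV; only
    ``max_trees``/``n_folds`` are meant to be scaled for problem size.
    """

    tree_complexity: int = 3
    learning_rate: float = 0.01
    bag_fraction: float = 0.5
    n_folds: int = 10
    max_trees: int = 1000
    min_trees_for_convergence: int = 100
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.learning_rate <= 1):
            raise ValueError("learning_rate must be in (0, 1]")
        if not (0 < self.bag_fraction <= 1):
            raise ValueError("bag_fraction must be in (0, 1]")
        if self.tree_complexity < 1:
            raise ValueError("tree_complexity must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    def lgb_params(self, seed: int) -> dict:
        return {
            "objective": "binary",
            "learning_rate": self.learning_rate,
            "max_depth": self.tree_complexity,
            "num_leaves": 2**self.tree_complexity,
            "bagging_fraction": self.bag_fraction,
            "bagging_freq": 1,
            "bagging_seed": seed,
            "feature_fraction": 1.0,
            "min_data_in_leaf": 5,
            "min_sum_hessian_in_leaf": 1e-3,
            "min_gain_to_split": 0.0,
            "verbose": -1,
            "seed": seed,
            "deterministic": True,
            "force_row_wise": True,
            "num_threads": 1,
        }


@dataclass
class BRTResult:
    """One species' fitted BRT and its summaries."""

    species_id: str
    settings: BRTSettings
    converged: bool
    is_null: bool = False
    n_trees: int = 0
    cv_deviance_explained: float = np.nan
    contributions: pd.Series | None = None
    curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    n_locations: int = 0
    n_presences: int = 0
    reason: str = ""
    cv_deviance_curve: np.ndarray | None = field(default=None, repr=False)
    booster: "lgb.Booster | None" = field(default=None, repr=False)
    feature_names: list[str] = field(default_factory=list, repr=False)
    X_train: np.ndarray | None = field(default=None, repr=False)


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    """Mean binomial deviance, 2x the mean negative log-likelihood."""
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_species_brt(
    y,
    X: pd.DataFrame,
    settings: BRTSettings,
    species_id: str = "",
    seed: int | None = None,
) -> BRTResult:
    """Fit one species' boosted regression tree.

    Rows with missing response (NA presence flags) are dropped.  All-0 or
    all-1 responses produce a non-converged result without a fit; a class
    smaller than the fold count raises :class:`StratifiedFoldError`.
    Convergence requires the selected tree count to reach
    ``min_trees_for_convergence`` and at least 5 presences and 5 absences.
    """
    seed = settings.seed if seed is None else seed
    feature_names = [c for c in X.columns]
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    keep = ~np.isnan(ya)
    Xa, ya = Xa[keep], ya[keep]
    if not np.isin(ya, (0.0, 1.0)).all():
        raise ValueError("y must contain only 0/1 (after dropping NA)")
    npos, nneg = int(ya.sum()), int(len(ya) - ya.sum())

    base = BRTResult(species_id=species_id, settings=settings, converged=False,
                     n_locations=len(ya), n_presences=npos,
                     feature_names=feature_names)
    if npos == 0 or nneg == 0:
        base.reason = "single-class response"
        return base
    if min(npos, nneg) < 5:
        base.reason = f"too few cases in a class ({min(npos, nneg)} < 5)"
        return base
    if min(npos, nneg) < settings.n_folds:
        raise StratifiedFoldError(
            f"{species_id or 'response'}: minority class ({min(npos, nneg)}) "
            f"smaller than n_folds ({settings.n_folds})"
        )

    params = settings.lgb_params(seed)
    skf = StratifiedKFold(n_splits=settings.n_folds, shuffle=True,
                          random_state=seed % (2**31))
    dev = np.zeros(settings.max_trees)
    null_dev = 0.0
    n_total = len(ya)
    for fold, (tr, te) in enumerate(skf.split(Xa, ya)):
        dtrain = lgb.Dataset(Xa[tr], label=ya[tr], params={"verbose": -1})
        dtest = lgb.Dataset(Xa[te], label=ya[te], reference=dtrain)
        evals: dict = {}
        lgb.train(params | {"bagging_seed": seed + fold, "seed": seed + fold},
                  dtrain, num_boost_round=settings.max_trees,
                  valid_sets=[dtest],
                  callbacks=[lgb.record_evaluation(evals)])
        logloss = np.asarray(evals["valid_0"]["binary_logloss"])
        w = len(te) / n_total
        dev += 2.0 * logloss * w
        null_dev += _binomial_deviance(ya[te], np.full(len(te), ya[tr].mean())) * w

    # smooth the CV curve before taking the argmin: the raw minimum of a
    # noisy curve is biased low (specious "deviance explained", worst for
    # small samples), and smoothing is how CV-curve tree selection is
    # conventionally stabilized
    window = max(5, settings.max_trees // 10)
    kernel = np.ones(window) / window
    dev_s = np.convolve(np.pad(dev, (window // 2, window - 1 - window // 2),
                               mode="edge"), kernel, mode="valid")
    best = int(np.argmin(dev_s))
    n_trees = best + 1

    # evaluate the deviance explained on an independent CV split at the
    # *fixed* selected stage: the minimum of the selection curve itself is
    # biased low (winner's curse, worst for small samples) and would fake
    # deviance explained on pure-noise responses
    skf_eval = StratifiedKFold(n_splits=settings.n_folds, shuffle=True,
                               random_state=(seed + 7919) % (2**31))
    cv_dev = 0.0
    null_dev_eval = 0.0
    for fold, (tr, te) in enumerate(skf_eval.split(Xa, ya)):
        dtrain = lgb.Dataset(Xa[tr], label=ya[tr], params={"verbose": -1})
        m = lgb.train(params | {"bagging_seed": seed + 101 + fold,
                                "seed": seed + 101 + fold},
                      dtrain, num_boost_round=n_trees)
        w = len(te) / n_total
        p = 1.0 / (1.0 + np.exp(-m.predict(Xa[te], raw_score=True)))
        cv_dev += _binomial_deviance(ya[te], p) * w
        null_dev_eval += _binomial_deviance(
            ya[te], np.full(len(te), ya[tr].mean())) * w
    cv_expl = (100.0 * (1.0 - cv_dev / null_dev_eval)
               if null_dev_eval > 0 else np.nan)

    dall = lgb.Dataset(Xa, label=ya, params={"verbose": -1})
    booster = lgb.train(params, dall, num_boost_round=n_trees)
    gain = booster.feature_importance(importance_type="gain")
    total_gain = gain.sum()

    res = replace(base)
    res.n_trees = n_trees
    res.cv_deviance_explained = cv_expl
    res.cv_deviance_curve = dev
    res.booster = booster
    res.X_train = Xa
    if total_gain > 0:
        res.contributions = pd.Series(100.0 * gain / total_gain, index=feature_names)
    res.converged = (
        n_trees >= settings.min_trees_for_convergence
        and min(npos, nneg) >= 5
        and total_gain > 0
    )
    if not res.converged and not res.reason:
        res.reason = ("no informative splits" if total_gain == 0
                      else f"selected tree count {n_trees} below "
                           f"{settings.min_trees_for_convergence}")
    return res


def relative_contributions(fit: BRTResult) -> pd.Series:
    """Per-correlate percent contributions (split-gain shares x 100)."""
    if fit.booster is None:
        raise ValueError("no fitted model (non-converged result)")
    gain = fit.booster.feature_importance(importance_type="gain")
    total = gain.sum()
    if total == 0:
        return pd.Series(np.zeros(len(fit.feature_names)), index=fit.feature_names)
    return pd.Series(100.0 * gain / total, index=fit.feature_names)


def partial_dependence(
    fit: BRTResult,
    correlate: str,
    grid: np.ndarray | None = None,
    n_grid: int = 100,
) -> pd.DataFrame:
    """Partial-dependence curve of one correlate.

    At each grid value g the model's raw (logit-scale) prediction is
    averaged over all training rows with the correlate fixed to g; the
    probability scale is the inverse-logit of that average.  The default
    grid spans the observed range with ``n_grid`` points.
    """
    if fit.booster is None or fit.X_train is None:
        raise ValueError("no fitted model (non-converged result)")
    if correlate not in fit.feature_names:
        raise KeyError(
            f"unknown correlate {correlate!r}; valid names: {fit.feature_names}")
    j = fit.feature_names.index(correlate)
    col = fit.X_train[:, j]
    if grid is None:
        lo, hi = float(col.min()), float(col.max())
        if hi <= lo:
            lo, hi = lo - 0.5, hi + 0.5
        grid = np.linspace(lo, hi, n_grid)
    grid = np.asarray(grid, dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    Xw = fit.X_train.copy()
    logit = np.empty(len(grid))
    for i, g in enumerate(grid):
        Xw[:, j] = g
        logit[i] = fit.booster.predict(Xw, raw_score=True).mean()
    return pd.DataFrame({"x": grid, "logit": logit, "prob": expit(logit)})


def null_randomize(y, range_mask, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Permute presences/absences uniformly among in-range locations.

    Out-of-range entries are untouched and the in-range presence total is
    conserved; this is the within-range null used to check that observed
    trait-contribution patterns exceed chance.
    """
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, 9)
    ya = np.asarray(y, dtype=float).copy()
    mask = np.asarray(range_mask, dtype=bool)
    if mask.shape != ya.shape:
        raise ValueError("range_mask must match y in shape")
    if not mask.any():
        raise ValueError("range mask is empty: nothing to permute")
    ya[mask] = rng.permutation(ya[mask])
    return ya


def run_all_species(
    matrix: pd.DataFrame,
    correlates: pd.DataFrame,
    traits: pd.DataFrame,
    settings: BRTSettings,
    null: bool = False,
    hulls: dict[str, RangeHull] | None = None,
    within_range_only: bool = True,
    curve_correlates: tuple[str, ...] | None = HEADLINE_CORRELATES,
) -> list[BRTResult]:
    """Fit one BRT per species (optionally the within-range null).

    Each species is fit on the locations inside its range hull (the
    default; set ``within_range_only=False`` to use all locations).  With
    ``null=True`` each species' labels are first permuted uniformly within
    its range — a single randomization per species.  Per-species failures
    are converted to non-converged results; the run always completes.
    """
    X = correlates[[c for c in CORRELATE_COLUMNS if c in correlates.columns]]
    results: list[BRTResult] = []
    for j, sp in enumerate(matrix.columns):
        y = matrix[sp].to_numpy(dtype=float)
        if hulls is not None and sp in hulls:
            mask = within_range(correlates, hulls[sp])
        else:
            mask = np.ones(len(y), dtype=bool)
        sp_seed = int(substream(settings.seed, 10, j).integers(2**31))
        if null:
            valid = mask & ~np.isnan(y)
            if valid.any():
                y = null_randomize(y, valid, substream(settings.seed, 11, j))
        rows = mask if within_range_only else np.ones(len(y), dtype=bool)
        try:
            res = fit_species_brt(y[rows], X.loc[rows], settings,
                                  species_id=sp, seed=sp_seed)
        except StratifiedFoldError as exc:
            res = BRTResult(species_id=sp, settings=settings, converged=False,
                            n_locations=int(rows.sum()),
                            n_presences=int(np.nansum(y[rows])),
                            reason=str(exc), feature_names=list(X.columns))
        res.is_null = null
        if res.converged and curve_correlates:
            for c in curve_correlates:
                if c in res.feature_names:
                    res.curves[c] = partial_dependence(res, c)
        results.append(res)
    n_fail = sum(not r.converged for r in results)
    if n_fail:
        warnings.warn(f"{n_fail}/{len(results)} species did not converge", stacklevel=2)
    return results


def results_to_frame(results: list[BRTResult]) -> pd.DataFrame:
    """Combined per-species table: convergence, tree count, CV deviance and
    one column per correlate contribution."""
    rows = []
    for r in results:
        row = {
            "species_id": r.species_id,
            "converged": r.converged,
            "is_null": r.is_null,
            "n_trees": r.n_trees,
            "n_locations": r.n_locations,
            "n_presences": r.n_presences,
            "cv_deviance_explained": r.cv_deviance_explained,
            "reason": r.reason,
        }
        if r.contributions is not None:
            row.update({f"contrib_{c}": v for c, v in r.contributions.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def curves_to_frame(results: list[BRTResult]) -> pd.DataFrame:
    """Long-format partial-dependence curves (species, correlate, x, logit, prob)."""
    parts = []
    for r in results:
        for c, cur in r.curves.items():
            d = cur.copy()
            d.insert(0, "correlate", c)
            d.insert(0, "species_id", r.species_id)
            parts.append(d)
    if not parts:
        return pd.DataFrame(columns=["species_id", "correlate", "x", "logit", "prob"])
    return pd.concat(parts, ignore_index=True)
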