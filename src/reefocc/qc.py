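"""Quality control of visual-survey fish data.

Four checks run before any occurrence modelling:

1. **Detectability proxy** — for each (species, location) with pooled
   presence, ``P`` is the fraction of replicate samples where the species
   was recorded (a species seen on 1/4 transects has P = 0.25; on 4/4,
   P = 1).  ``P`` is modelled as binomial counts in a hierarchical logistic
   regression with random intercepts for data source and for genus nested
   within family, and a log(transect area) offset; three fixed-effect
   specifications of increasing geographic content are compared on AICc.
2. **False absences** — on the distance-banded subset, the probability
   that a species is recorded *only* beyond 5 m (hence scored absent on
   the transect proper) is compared across fishing-intensity levels to
   detect diver avoidance under fishing pressure.
3. **Source / temporal effects** — PERMANOVA on Bray-Curtis distances
   between per-location species detection-frequency profiles, grouped by
   data source.
4. **Missingness placement** — a PCA of the standardized correlates plus a
   permutation test of whether locations with missing fish data sit apart
   from the rest in the leading component plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .glmm import BinomialGLMMResult, fit_binomial_glmm
from .synthetic import substream

__all__ = [
    "detection_proportion",
    "fit_detectability_model",
    "compare_detectability_models",
    "DetectModelFit",
    "false_absence_rate",
    "false_absence_trend_test",
    "permanova",
    "source_effect_test",
    "missingness_pca_check",
    "MissingnessPCA",
]

DETECT_MODELS = ("model1", "model2", "model3")
TRANSECT_AREA_REF = 250.0  # m^2


# ---------------------------------------------------------------------------
# detectability proxy
# ---------------------------------------------------------------------------

def detection_proportion(survey: pd.DataFrame) -> pd.DataFrame:
    """Per-(species, location) detection proportion P, given presence.

    NA-flagged records (restricted species lists) are excluded before
    counting; rows are emitted only where the pooled presence is 1, so
    0 < P <= 1 always.  Locations contributing zero usable replicates for a
    species are skipped.
    """
    rec = survey.dropna(subset=["detected"]).copy()
    rec["detected"] = rec["detected"].astype(float)
    g = rec.groupby(["species_id", "location_id"], sort=True)
    out = g.agg(
        detected_count=("detected", "sum"),
        n_replicates=("detected", "size"),
        transect_area=("transect_area", "mean"),
        data_source=("data_source", "first"),
        fishing_intensity=("fishing_intensity", "first"),
    ).reset_index()
    out = out[out["n_replicates"] > 0]
    out = out[out["detected_count"] > 0].reset_index(drop=True)
    out["P"] = out["detected_count"] / out["n_replicates"]
    return out


_REGION_BREAKS = (100.0, 145.0)  # lon cuts: WIO | IAA | WPacific


def _region(lon: np.ndarray) -> np.ndarray:
    return np.where(lon < _REGION_BREAKS[0], "WIO",
                    np.where(lon < _REGION_BREAKS[1], "IAA", "WPac"))


@dataclass
class DetectModelFit:
    """One detectability model fit plus its information-theoretic scores."""

    label: str
    result: BinomialGLMMResult
    aicc: float
    waicc: float | None = None
    degraded: bool = False
    residuals_by_location: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def _detect_design(records: pd.DataFrame, traits: pd.DataFrame,
                   correlates: pd.DataFrame | None, model: str) -> pd.DataFrame:
    df = records.merge(
        traits[["species_id", "family", "genus", "body_size",
                "mobility", "schooling", "water_level"]],
        on="species_id", how="left", validate="many_to_one")
    if model in ("model2", "model3"):
        if correlates is None:
            raise ValueError(f"{model} needs the correlate table (geography covariates)")
        cols = ["location_id", "lon", "dist_to_IAA"]
        if model == "model3":
            cols += ["dist_to_land", "reef_area_50km", "sst_sdev", "human_impact"]
        df = df.merge(correlates[cols], on="location_id", how="left", validate="many_to_one")
        df["region"] = _region(df["lon"].to_numpy())
    return df


def fit_detectability_model(
    records: pd.DataFrame,
    traits: pd.DataFrame,
    correlates: pd.DataFrame | None = None,
    model: str = "model1",
) -> DetectModelFit:
    """Fit one of the three detectability model specifications.

    * ``model1``: body size and behaviour (mobility, schooling, water level);
    * ``model2``: model1 + region and distance to the Coral Triangle;
    * ``model3``: model2 + the leading occurrence correlates (distance to
      land, reef area within 50 km, SST seasonality, human impact), taken
      as location-level values.

    All share binomial counts (detections out of replicates), a
    log(transect area) offset and random intercepts for data source,
    family, and genus (nested via the additive family + genus terms).
    Singular random-effect fits fall back to fixed effects only, flagged
    ``degraded``.
    """
    if model not in DETECT_MODELS:
        raise ValueError(f"model must be one of {DETECT_MODELS}, got {model!r}")
    df = _detect_design(records, traits, correlates, model)
    if df["data_source"].nunique() < 2 or df["family"].nunique() < 2:
        warnings.warn("fewer than 2 data sources or families: random effects weakly identified",
                      stacklevel=2)

    X = pd.DataFrame({"intercept": np.ones(len(df))})
    X["body_size"] = df["body_size"].to_numpy(dtype=float)
    for cat in ("mobility", "schooling", "water_level"):
        dummies = pd.get_dummies(df[cat].astype(str), prefix=cat, drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    if model in ("model2", "model3"):
        X = pd.concat([X, pd.get_dummies(df["region"], prefix="region",
                                         drop_first=True, dtype=float)], axis=1)
        X["dist_to_IAA"] = _zscore(df["dist_to_IAA"])
    if model == "model3":
        for c in ("dist_to_land", "reef_area_50km", "sst_sdev", "human_impact"):
            X[c] = _zscore(df[c])

    offset = np.log(df["transect_area"].to_numpy(dtype=float) / TRANSECT_AREA_REF)
    groups = {
        "data_source": df["data_source"].to_numpy(),
        "family": df["family"].to_numpy(),
        "genus": df["genus"].to_numpy(),
    }
    res = fit_binomial_glmm(df["detected_count"], df["n_replicates"], X,
                            groups=groups, offset=offset)
    degraded = False
    if res.singular and all(v < 1e-5 for v in res.vc.values()):
        res = fit_binomial_glmm(df["detected_count"], df["n_replicates"], X,
                                groups=None, offset=offset)
        degraded = True

    from .traits import aicc  # closed-form AICc
    a = aicc(res.loglik, res.k_params, res.nobs)
    fitted = _fitted_p(res, X, offset, groups, degraded)
    resid = pd.Series(df["P"].to_numpy() - fitted if "P" in df else
                      df["detected_count"].to_numpy() / df["n_replicates"].to_numpy() - fitted,
                      index=df["location_id"])
    return DetectModelFit(
        label=model, result=res, aicc=a, degraded=degraded,
        residuals_by_location=resid.groupby(level=0).mean(),
    )


def _zscore(s: pd.Series) -> np.ndarray:
    x = s.to_numpy(dtype=float)
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _fitted_p(res: BinomialGLMMResult, X: pd.DataFrame, offset, groups, degraded) -> np.ndarray:
    from scipy.special import expit
    eta = np.asarray(X, dtype=float) @ res.params.to_numpy() + offset
    if not degraded:
        for name, re in res.random_effects.items():
            eta += pd.Series(groups[name]).map(re).fillna(0.0).to_numpy()
    return expit(eta)


def compare_detectability_models(
    records: pd.DataFrame,
    traits: pd.DataFrame,
    correlates: pd.DataFrame | None = None,
    models: tuple[str, ...] = DETECT_MODELS,
) -> tuple[pd.DataFrame, dict[str, DetectModelFit]]:
    """Fit the requested detectability models on identical rows and return
    an AICc table (with wAICc summing to 1) plus the fits."""
    from .traits import waicc
    fits = {m: fit_detectability_model(records, traits, correlates, m) for m in models}
    a = np.array([fits[m].aicc for m in models])
    w = waicc(a)
    for m, wi in zip(models, w):
        fits[m].waicc = float(wi)
    table = pd.DataFrame({
        "model": models,
        "k": [fits[m].result.k_params for m in models],
        "loglik": [fits[m].result.loglik for m in models],
        "AICc": a,
        "dAICc": a - a.min(),
        "wAICc": w,
        "degraded": [fits[m].degraded for m in models],
    })
    return table, fits


# ---------------------------------------------------------------------------
# false absences vs fishing intensity
# ---------------------------------------------------------------------------

@dataclass
class FalseAbsenceResult:
    """Rates of beyond-5m-only records (false absences within 5 m)."""

    by_species: pd.DataFrame   # species_id x fishing_intensity rates
    summary: pd.DataFrame      # group (all | targeted_large) x intensity
    empty: bool = False


def false_absence_rate(survey: pd.DataFrame, traits: pd.DataFrame | None = None
                       ) -> FalseAbsenceResult:
    """Rate of transects where a species was recorded only beyond 5 m.

    Per species x fishing-intensity level, the rate is (transects with
    beyond-5m-only records) / (transects with any record).  Summaries pool
    all species and, when traits are given, the targeted/large subset
    (body size > 50 cm).  Without distance-band data the result is
    explicitly empty, never a table of zeros.
    """
    det = survey[(survey["detected"] == 1)].dropna(subset=["distance_band"])
    if len(det) == 0:
        empty_sp = pd.DataFrame(columns=["species_id", "fishing_intensity",
                                         "n_records", "n_beyond_only", "rate"])
        empty_sum = pd.DataFrame(columns=["group", "fishing_intensity",
                                          "n_records", "n_beyond_only", "rate"])
        return FalseAbsenceResult(by_species=empty_sp, summary=empty_sum, empty=True)

    det = det.assign(beyond_only=(det["distance_band"] == "beyond-5m").astype(int))
    by_sp = (det.groupby(["species_id", "fishing_intensity"])
             .agg(n_records=("beyond_only", "size"), n_beyond_only=("beyond_only", "sum"))
             .reset_index())
    by_sp["rate"] = by_sp["n_beyond_only"] / by_sp["n_records"]

    def pool(sub: pd.DataFrame, label: str) -> pd.DataFrame:
        g = (sub.groupby("fishing_intensity")
             .agg(n_records=("beyond_only", "size"), n_beyond_only=("beyond_only", "sum"))
             .reset_index())
        g.insert(0, "group", label)
        g["rate"] = g["n_beyond_only"] / g["n_records"]
        return g

    parts = [pool(det, "all")]
    if traits is not None:
        large = set(traits.loc[traits["body_size"] > 50, "species_id"])
        sub = det[det["species_id"].isin(large)]
        if len(sub):
            parts.append(pool(sub, "targeted_large"))
    return FalseAbsenceResult(by_species=by_sp, summary=pd.concat(parts, ignore_index=True))


def false_absence_trend_test(
    survey: pd.DataFrame,
    traits: pd.DataFrame | None = None,
    group: str = "all",
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test of a false-absence trend along fishing intensity.

    The statistic is the record-weighted least-squares slope of the
    beyond-5m-only rate on the intensity score; the null shuffles the
    location -> intensity assignment.  Returns (slope, two-sided p with the
    add-one correction).
    """
    det = survey[(survey["detected"] == 1)].dropna(subset=["distance_band"]).copy()
    if traits is not None and group == "targeted_large":
        large = set(traits.loc[traits["body_size"] > 50, "species_id"])
        det = det[det["species_id"].isin(large)]
    if len(det) == 0:
        return np.nan, np.nan
    det["beyond_only"] = (det["distance_band"] == "beyond-5m").astype(float)
    loc_int = det.groupby("location_id")["fishing_intensity"].first()

    def slope(intensity_map: pd.Series) -> float:
        fi = det["location_id"].map(intensity_map).to_numpy(dtype=float)
        y = det["beyond_only"].to_numpy()
        x = fi - fi.mean()
        denom = np.sum(x**2)
        return float(np.sum(x * (y - y.mean())) / denom) if denom > 0 else 0.0

    obs = slope(loc_int)
    rng = substream(seed, 7)
    vals = loc_int.to_numpy().copy()
    count = 0
    for _ in range(n_perm):
        rng.shuffle(vals)
        if abs(slope(pd.Series(vals, index=loc_int.index))) >= abs(obs) - 1e-15:
            count += 1
    return obs, (count + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def permanova(dist: np.ndarray, grouping, n_perm: int = 999, seed: int = 0
              ) -> tuple[float, float]:
    """PERMANOVA pseudo-F and permutation p on a distance matrix.

    The among/within partition of the squared distances and the label
    permutations are delegated to scikit-bio; p uses the add-one
    correction ``(count of permuted F >= observed + 1) / (n_perm + 1)``,
    so the minimum attainable p is ``1/(n_perm + 1)``.
    """
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.distance import permanova as _skbio_permanova

    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10) or (d < -1e-12).any():
        raise ValueError("distance matrix must be symmetric and non-negative")
    labels = np.asarray(grouping)
    if len(labels) != d.shape[0]:
        raise ValueError("grouping length must match the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    for g, c in zip(uniq, counts):
        if c < 2:
            raise ValueError(f"group {g!r} has a single member")

    dm = DistanceMatrix(d, ids=[str(i) for i in range(d.shape[0])])
    try:
        res = _skbio_permanova(dm, labels, permutations=n_perm, seed=seed)
    except TypeError:  # older scikit-bio without a seed argument
        state = np.random.get_state()
        np.random.seed(seed & 0xFFFFFFFF)
        try:
            res = _skbio_permanova(dm, labels, permutations=n_perm)
        finally:
            np.random.set_state(state)
    return float(res["test statistic"]), float(res["p-value"])


def detection_frequency_profiles(survey: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-location species detection-frequency vectors and source labels.

    Frequencies are detections / replicates per (location, species) on
    non-NA records; locations with no detections at all are dropped (their
    Bray-Curtis distances are undefined).
    """
    rec = survey.dropna(subset=["detected"])
    freq = rec.pivot_table(index="location_id", columns="species_id",
                           values="detected", aggfunc="mean")
    freq = freq.fillna(0.0)
    keep = freq.sum(axis=1) > 0
    freq = freq[keep]
    src = (rec.groupby("location_id")["data_source"].first().loc[freq.index]).to_numpy()
    return freq.to_numpy(dtype=float), src


def source_effect_test(survey: pd.DataFrame, n_perm: int = 999, seed: int = 0
                       ) -> tuple[float, float]:
    """Data-source effect on composition: PERMANOVA on Bray-Curtis
    distances between location detection-frequency profiles."""
    profiles, src = detection_frequency_profiles(survey)
    d = squareform(pdist(profiles, metric="braycurtis"))
    return permanova(d, src, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# missing-data placement in correlate space
# ---------------------------------------------------------------------------

@dataclass
class MissingnessPCA:
    """PCA summary of where missing-data locations sit in correlate space."""

    scores: pd.DataFrame          # location scores on PC1/PC2
    var_explained: np.ndarray     # % per component, sums to 100
    centroid_distance: float
    p_value: float
    dropped_columns: list[str]


def missingness_pca_check(
    correlates: pd.DataFrame,
    missing_mask,
    n_perm: int = 999,
    seed: int = 0,
) -> MissingnessPCA:
    """Test whether missing-data locations cluster in correlate space.

    Locations are scored on the principal axes of the standardized
    correlates; the statistic is the distance between the centroids of
    missing and non-missing locations in the PC1-PC2 plane, with a
    permutation p (add-one correction).  Constant columns are dropped with
    a warning.
    """
    from .synthetic import CORRELATE_COLUMNS
    mask = np.asarray(missing_mask, dtype=bool)
    cols = [c for c in CORRELATE_COLUMNS if c in correlates.columns]
    if len(cols) < 2:
        raise ValueError("need at least 2 correlates for a PCA")
    Xdf = correlates[cols]
    sd = Xdf.std(ddof=0)
    dropped = list(sd.index[sd == 0])
    if dropped:
        warnings.warn(f"dropping constant correlate columns: {dropped}", stacklevel=2)
        Xdf = Xdf.drop(columns=dropped)
    X = (Xdf - Xdf.mean()) / Xdf.std(ddof=0)

    pca = PCA()
    scores = pca.fit_transform(X.to_numpy())
    var_pct = pca.explained_variance_ratio_ * 100.0
    s2 = scores[:, :2]

    def centroid_dist(m: np.ndarray) -> float:
        if m.sum() == 0 or m.sum() == len(m):
            return 0.0
        return float(np.linalg.norm(s2[m].mean(axis=0) - s2[~m].mean(axis=0)))

    obs = centroid_dist(mask)
    rng = substream(seed, 8)
    perm = mask.copy()
    count = 0
    for _ in range(n_perm):
        rng.shuffle(perm)
        if centroid_dist(perm) >= obs - 1e-15:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MissingnessPCA(
        scores=pd.DataFrame(s2, columns=["PC1", "PC2"],
                            index=correlates["location_id"]
                            if "location_id" in correlates else None),
        var_explained=var_pct,
        centroid_distance=obs,
        p_value=p,
        dropped_columns=dropped,
    )
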