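"""Synthetic Indo-Pacific reef-fish survey generator.

The real compilation behind this kind of analysis (hundreds of locations,
thousands of replicate transects, a couple hundred species) is not
redistributable, so this module generates survey data with the statistical
structure the downstream analysis assumes:

* a location x correlate table whose covariates fall under four hypothesis
  families (biogeography, area, energy, human pressure), cross-correlated
  through a Gaussian copula but always with pairwise Pearson |r| < 0.7
  (the multicollinearity ceiling under which boosted regression trees are
  considered robust);
* a species trait table with log-uniform body sizes, range sizes positively
  coupled to body size, and categorical behaviour traits;
* convex-hull geographic ranges anchored on the survey domain;
* true occurrence probabilities that are piecewise-linear on the logit
  scale — the human-impact and SST-seasonality effects strengthen with log
  body size and weaken with range size, the reef-area effect does the
  opposite — with hard zeros outside each species' range hull;
* replicate-level detections with size/behaviour-dependent detectability
  and a log(transect area) offset, plus an optional beyond-5m "diver
  avoidance" band; and
* source-restricted missingness (some sources survey only a species
  subset), recorded as NA rather than absence.

Everything is deterministic given the master seed; per-stage substreams are
derived with :func:`substream`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri
from scipy.stats import norm

from .ranges import RangeHull, convex_hull_eoo, within_range, DEG2_TO_1E6KM2

__all__ = [
    "CORRELATE_COLUMNS",
    "HYPOTHESIS_MAP",
    "TrueModelParams",
    "PiecewiseEffect",
    "default_params",
    "generate_locations",
    "generate_species",
    "generate_ranges",
    "simulate_occurrence",
    "simulate_surveys",
    "apply_missingness",
    "make_restricted_lists",
    "pooled_presence",
    "size_class",
    "small_ranging_flag",
    "substream",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration (e.g. non-PSD correlation target)."""


# ---------------------------------------------------------------------------
# correlate schema
# ---------------------------------------------------------------------------

#: correlate -> hypothesis family, the partition used when BRT contributions
#: are aggregated to the four competing hypotheses.
HYPOTHESIS_MAP: dict[str, str] = {
    # biogeography: connectivity and position within range
    "dist_to_land": "biogeography",
    "dist_to_shelf_edge": "biogeography",
    "dist_to_margin": "biogeography",
    "rel_margin_dist": "biogeography",
    "rel_lon": "biogeography",
    "rel_lat": "biogeography",
    "dist_to_IAA": "biogeography",
    # habitat area, present and historical
    "reef_area": "area",
    "reef_perimeter": "area",
    "reef_area_10km": "area",
    "reef_area_50km": "area",
    "shelf_area_50km": "area",
    # energy: kinetic (SST) and potential (Chl a)
    "sst_mean": "energy",
    "sst_winter": "energy",
    "sst_summer": "energy",
    "sst_sdev": "energy",
    "chla_mean": "energy",
    "chla_sdev": "energy",
    # human pressure
    "present_threat": "human_pressure",
    "integrated_threat": "human_pressure",
    "human_impact": "human_pressure",
    "ocean_health": "human_pressure",
    "ohi_fisheries": "human_pressure",
    "ohi_artisanal": "human_pressure",
    "ohi_livelihoods": "human_pressure",
    "ohi_sense_place": "human_pressure",
    "ohi_biodiversity": "human_pressure",
    "ohi_coastal_protection": "human_pressure",
}

CORRELATE_COLUMNS: list[str] = list(HYPOTHESIS_MAP)

HYPOTHESES = ("biogeography", "area", "energy", "human_pressure")

#: survey domain (lon/lat box, degrees), Indo-Pacific-like extent
DOMAIN = (40.0, 190.0, -25.0, 25.0)
#: reference point standing in for the Indo-Australian Archipelago
IAA_POINT = (130.0, 0.0)
KM_PER_DEG = 111.195


def substream(seed: int, *keys: int) -> np.random.Generator:
    """Deterministic per-stage random substream of a master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *keys]))


# marginal transforms: copula column -> physical units.
# (kind, params): "lognorm" exp(mu + sigma*z); "norm" mu + sigma*z;
# "uniform" a + (b-a)*Phi(z); "ordinal" quantile cut of Phi(z)
_MARGINALS: dict[str, tuple] = {
    "dist_to_land": ("lognorm", 4.8, 1.0),
    "dist_to_shelf_edge": ("lognorm", 3.0, 1.0),
    "dist_to_margin": ("lognorm", 6.0, 0.8),
    "rel_margin_dist": ("uniform", 0.0, 1.0),
    "rel_lon": ("uniform", -1.0, 1.0),
    "rel_lat": ("uniform", -1.0, 1.0),
    "reef_area": ("lognorm", 2.0, 1.2),
    "reef_perimeter": ("lognorm", 1.5, 0.6),
    "reef_area_10km": ("lognorm", 4.0, 1.0),
    "reef_area_50km": ("lognorm", 6.6, 0.9),
    "shelf_area_50km": ("lognorm", 7.0, 0.8),
    "sst_mean": ("norm", 27.0, 1.5),
    "sst_winter": ("norm", 25.0, 1.8),
    "sst_summer": ("norm", 29.0, 1.2),
    "sst_sdev": ("lognorm", 0.3, 0.55),
    "chla_mean": ("lognorm", -1.2, 0.8),
    "chla_sdev": ("lognorm", -2.0, 0.8),
    "present_threat": ("ordinal", (0.35, 0.65, 0.85)),
    "integrated_threat": ("ordinal", (0.25, 0.55, 0.80)),
    "human_impact": ("lognorm", 2.6, 0.7),
    "ocean_health": ("norm", 60.0, 12.0),
    "ohi_fisheries": ("norm", 55.0, 15.0),
    "ohi_artisanal": ("norm", 62.0, 14.0),
    "ohi_livelihoods": ("norm", 58.0, 15.0),
    "ohi_sense_place": ("norm", 65.0, 13.0),
    "ohi_biodiversity": ("norm", 70.0, 12.0),
    "ohi_coastal_protection": ("norm", 63.0, 14.0),
}

#: columns derived from lon/lat rather than the copula
_DERIVED = ("dist_to_IAA",)


def _default_corr(columns: Sequence[str], rho_within: float, rho_between: float) -> np.ndarray:
    """Block-structured copula correlation target: moderate within-hypothesis,
    weak across; always well below the 0.7 ceiling after the monotone
    marginal transforms."""
    k = len(columns)
    r = np.full((k, k), rho_between)
    for i, a in enumerate(columns):
        for j, b in enumerate(columns):
            if HYPOTHESIS_MAP[a] == HYPOTHESIS_MAP[b]:
                r[i, j] = rho_within
    np.fill_diagonal(r, 1.0)
    return r


def generate_locations(
    n_loc: int,
    seed: int = 0,
    rho_within: float = 0.45,
    rho_between: float = 0.15,
    corr: np.ndarray | None = None,
) -> pd.DataFrame:
    """Generate the location x correlate table.

    Covariates are drawn through a Gaussian copula (latent MVN with a
    block-structured correlation target, or a user-supplied one) and mapped
    through per-column monotone marginals: log-normal for areas/distances,
    Gaussian for temperatures and index scores, uniform for relative
    positions, quantile cuts for ordinal threat classes.  ``dist_to_IAA`` is
    computed from the sampled coordinates.

    Raises
    ------
    ConfigurationError
        If the supplied correlation target is not symmetric positive
        semi-definite with unit diagonal.
    """
    if n_loc < 0:
        raise ValueError("n_loc must be >= 0")
    cop_cols = [c for c in CORRELATE_COLUMNS if c not in _DERIVED]
    if corr is None:
        corr = _default_corr(cop_cols, rho_within, rho_between)
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (len(cop_cols), len(cop_cols)):
        raise ConfigurationError(
            f"correlation target must be {len(cop_cols)}x{len(cop_cols)}, got {corr.shape}"
        )
    if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
        raise ConfigurationError("correlation target must be symmetric with unit diagonal")
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-10:
        raise ConfigurationError(
            f"correlation target is not positive semi-definite (min eigenvalue {eigvals.min():.3g})"
        )

    rng = substream(seed, 1)
    lon = rng.uniform(DOMAIN[0], DOMAIN[1], size=n_loc)
    lat = rng.uniform(DOMAIN[2], DOMAIN[3], size=n_loc)

    # latent MVN draw via eigendecomposition (tolerates PSD-but-singular targets)
    w, v = np.linalg.eigh(corr)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal(size=(n_loc, len(cop_cols))) @ root.T

    data: dict[str, np.ndarray] = {
        "location_id": np.array([f"L{i:04d}" for i in range(n_loc)]),
        "lon": lon,
        "lat": lat,
    }
    for j, col in enumerate(cop_cols):
        kind, *p = _MARGINALS[col]
        zi = z[:, j]
        if kind == "lognorm":
            data[col] = np.exp(p[0] + p[1] * zi)
        elif kind == "norm":
            data[col] = p[0] + p[1] * zi
        elif kind == "uniform":
            a, b = p
            data[col] = a + (b - a) * norm.cdf(zi)
        elif kind == "ordinal":
            cuts = ndtri(np.asarray(p[0]))
            data[col] = (np.searchsorted(cuts, zi) + 1).astype(float)
        else:  # pragma: no cover
            raise ConfigurationError(f"unknown marginal kind {kind!r}")
    data["dist_to_IAA"] = KM_PER_DEG * np.hypot(lon - IAA_POINT[0], lat - IAA_POINT[1])

    df = pd.DataFrame(data, columns=["location_id", "lon", "lat", *CORRELATE_COLUMNS])
    return df


# ---------------------------------------------------------------------------
# species traits
# ---------------------------------------------------------------------------

_FAMILIES = (
    "Acanthuridae", "Chaetodontidae", "Labridae", "Lutjanidae", "Lethrinidae",
    "Serranidae", "Scaridae", "Pomacentridae", "Mullidae", "Haemulidae",
)

_TRAIT_FREQS: dict[str, dict[str, float]] = {
    "trophic_group": {"FC": 0.08, "HD": 0.18, "HM": 0.07, "IM": 0.30,
                      "IS": 0.07, "OM": 0.12, "PK": 0.18},
    "home_range": {"Sed": 0.45, "Mob": 0.40, "VMob": 0.15},
    "mobility": {"low": 0.60, "high": 0.40},
    "diel_activity": {"diurnal": 0.80, "nocturnal": 0.20},
    "schooling": {"Sol": 0.35, "Pair": 0.15, "SmallG": 0.25, "MedG": 0.15, "LargeG": 0.10},
    "water_level": {"bottom": 0.50, "low": 0.30, "high": 0.20},
}

SIZE_CLASSES = ("<=15", "16-50", ">50")


def size_class(body_size) -> np.ndarray | str:
    """Body-size class label(s): ``<=15``, ``16-50`` or ``>50`` cm."""
    arr = np.asarray(body_size, dtype=float)
    out = np.where(arr <= 15, SIZE_CLASSES[0], np.where(arr <= 50, SIZE_CLASSES[1], SIZE_CLASSES[2]))
    return out.item() if np.isscalar(body_size) else out


def small_ranging_flag(traits: pd.DataFrame, within_class: bool = True) -> pd.Series:
    """Membership of the first quartile of geographic range sizes.

    By default the quartile is computed within each body-size class (the
    convention that matches a handful of small-ranging *large* fishes);
    ``within_class=False`` uses a single global quartile.
    """
    if within_class:
        grp = traits.groupby(pd.Series(size_class(traits["body_size"]), index=traits.index))
        q1 = grp["range_size"].transform(lambda s: s.quantile(0.25))
    else:
        q1 = pd.Series(traits["range_size"].quantile(0.25), index=traits.index)
    return traits["range_size"] <= q1


def generate_species(
    n_sp: int,
    seed: int = 0,
    size_range: tuple[float, float] = (4.0, 180.0),
    coupling: bool = True,
    coupling_strength: float = 0.45,
    range_noise: float = 0.5,
    trait_freqs: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Generate the species trait table.

    Body sizes (maximum adult total length, cm) are log-uniform on
    ``size_range``; range sizes (extent of occurrence, 10^6 km^2) are
    log-normal with a positive log-log coupling to body size (large-bodied
    species tend to have large ranges) plus noise; categorical traits are
    sampled from configurable frequencies; genera are nested within
    families.
    """
    if n_sp < 1:
        raise ValueError("n_sp must be >= 1")
    freqs = {**_TRAIT_FREQS, **(trait_freqs or {})}
    rng = substream(seed, 2)

    log_size = rng.uniform(np.log(size_range[0]), np.log(size_range[1]), size=n_sp)
    body_size = np.exp(log_size)
    z_size = (log_size - log_size.mean()) / max(log_size.std(), 1e-12)
    # extent-of-occurrence scale of widely surveyed reef fishes: tens of
    # 10^6 km^2, upper tail near the whole-domain extent
    b = coupling_strength if coupling else 0.0
    log_range = np.log(85.0) + b * z_size + range_noise * rng.standard_normal(n_sp)
    range_size = np.clip(np.exp(log_range), 40.0, 140.0)

    family = rng.choice(_FAMILIES, size=n_sp)
    n_genus = {f: 2 + (i % 3) for i, f in enumerate(_FAMILIES)}
    genus = np.array([f"{f[:4]}_g{rng.integers(1, n_genus[f] + 1)}" for f in family])

    data = {
        "species_id": np.array([f"SP{i:03d}" for i in range(n_sp)]),
        "family": family,
        "genus": genus,
        "body_size": body_size,
        "range_size": range_size,
    }
    for trait, fr in freqs.items():
        labels = list(fr)
        p = np.array([fr[k] for k in labels], dtype=float)
        data[trait] = rng.choice(labels, size=n_sp, p=p / p.sum())
    return pd.DataFrame(data)


def generate_ranges(
    traits: pd.DataFrame,
    locations: pd.DataFrame,
    seed: int = 0,
    n_points: int = 40,
    update_traits: bool = True,
    max_retries: int = 25,
) -> dict[str, RangeHull]:
    """Build a convex-hull range per species, anchored on survey locations.

    Each species' occurrence records are drawn uniformly on a disc whose
    radius matches the species' target range size; the disc is centred near
    a randomly chosen survey location so the hull overlaps the sampled
    domain.  If ``update_traits``, ``traits['range_size']`` is replaced by
    the exact hull EOO so trait table and geometry agree.
    """
    rng = substream(seed, 3)
    hulls: dict[str, RangeHull] = {}
    has_locs = len(locations) > 0
    areas = []
    for _, row in traits.iterrows():
        target_deg2 = row["range_size"] / DEG2_TO_1E6KM2
        radius = np.sqrt(target_deg2 / np.pi)
        hull = None
        for attempt in range(max_retries):
            if has_locs:
                anchor = locations.iloc[rng.integers(len(locations))]
                # keep the range centred on the survey domain: jitter a
                # little, then clamp so coverage tracks range size
                cx = np.clip(anchor["lon"] + rng.normal(0, radius * 0.15),
                             DOMAIN[0], DOMAIN[1])
                cy = np.clip(anchor["lat"] + rng.normal(0, radius * 0.15),
                             DOMAIN[2], DOMAIN[3])
            else:
                cx = rng.uniform(DOMAIN[0], DOMAIN[1])
                cy = rng.uniform(DOMAIN[2], DOMAIN[3])
            r_eff = radius * (1.0 + 0.2 * attempt / max_retries)
            u = rng.random(n_points)
            th = rng.uniform(0, 2 * np.pi, n_points)
            pts = np.column_stack([cx + r_eff * np.sqrt(u) * np.cos(th),
                                   cy + r_eff * np.sqrt(u) * np.sin(th)])
            cand = convex_hull_eoo(pts, species_id=row["species_id"], area_scale=DEG2_TO_1E6KM2)
            if not has_locs or within_range(locations, cand).any():
                hull = cand
                break
        if hull is None:
            hull = cand  # last attempt, no overlap: caller handles all-absent species
        hulls[row["species_id"]] = hull
        areas.append(hull.area)
    if update_traits:
        traits = traits  # in-place update by design: geometry is authoritative
        traits["range_size"] = np.maximum(areas, 0.5)
    return hulls


# ---------------------------------------------------------------------------
# true occurrence model
# ---------------------------------------------------------------------------

@dataclass
class PiecewiseEffect:
    """Hinge effect on the logit scale: below ``threshold`` the covariate
    contributes ``slope_before`` per SD, above it ``slope_after`` per SD
    (continuous at the threshold).  ``threshold_shift`` moves the
    species-specific threshold by that many raw units per SD of log body
    size, so e.g. a negative shift plants *lower* human-impact thresholds
    for larger-bodied species."""

    threshold: float
    slope_before: float
    slope_after: float
    threshold_shift: float = 0.0


@dataclass
class TrueModelParams:
    """Generating parameters of the synthetic occurrence/detection process.

    Slopes are per standard deviation of the correlate over locations.
    ``size_scaling[c]`` multiplies the slope of correlate ``c`` by
    ``(1 + k * z_logsize)`` and ``range_scaling[c]`` by ``(1 - k * z_logrange)``,
    where z-scores are computed over the species table; this is how the
    "human pressure and seasonality hit large-bodied, small-ranging species
    hardest, area favours small species" structure is planted.
    """

    intercept: float = 0.4
    linear_slopes: dict[str, float] = field(default_factory=lambda: {
        "dist_to_land": -0.8,
        "reef_area_50km": 0.9,
        "chla_mean": 0.35,
        "rel_margin_dist": 0.7,
        "dist_to_IAA": -0.35,
    })
    piecewise: dict[str, PiecewiseEffect] = field(default_factory=lambda: {
        "human_impact": PiecewiseEffect(threshold=12.0, slope_before=0.0,
                                        slope_after=-1.3, threshold_shift=-2.5),
        "sst_sdev": PiecewiseEffect(threshold=1.6, slope_before=-0.8, slope_after=0.0),
    })
    size_scaling: dict[str, float] = field(default_factory=lambda: {
        "human_impact": 1.1,
        "sst_sdev": 0.9,
        "reef_area_50km": -0.6,
        "dist_to_land": -0.4,
    })
    range_scaling: dict[str, float] = field(default_factory=lambda: {
        "human_impact": 0.5,
        "sst_sdev": 0.4,
    })
    # detectability (logit scale)
    detect_intercept: float = 1.6
    detect_size_slope: float = -0.006  # per cm of maximum adult length
    detect_offsets: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "mobility": {"high": -0.29},
        "schooling": {"Sol": -0.56},
        "water_level": {"low": -0.40, "high": -1.04},
    })
    detect_area_coef: float = 1.0       # coefficient on log(area / area_ref)
    transect_area_ref: float = 250.0    # m^2
    # beyond-5m band ("diver avoidance")
    avoidance_base: float = 0.10
    avoidance_fishing_effect: float = 0.0   # per fishing-intensity step above 1

    def validate(self) -> None:
        vals = [self.intercept, self.detect_intercept, self.detect_size_slope,
                *self.linear_slopes.values(), *self.size_scaling.values(),
                *self.range_scaling.values()]
        for pw in self.piecewise.values():
            vals += [pw.threshold, pw.slope_before, pw.slope_after]
        if not np.all(np.isfinite(vals)):
            raise ConfigurationError("TrueModelParams contains non-finite values")

    def to_dict(self) -> dict:
        return asdict(self)


def default_params() -> TrueModelParams:
    """The default study-condition parameter set (see docs/methods.md)."""
    return TrueModelParams()


@dataclass
class OccurrenceSim:
    """Presence/absence matrix plus the generating truth (for tests)."""

    matrix: pd.DataFrame     # locations x species, int 0/1
    prob: pd.DataFrame       # true occurrence probability
    in_range: pd.DataFrame   # bool range mask


def true_logit(
    traits_row: pd.Series,
    correlates: pd.DataFrame,
    params: TrueModelParams,
    z_size: float,
    z_range: float,
) -> np.ndarray:
    """True occurrence logit for one species across all locations."""
    eta = np.full(len(correlates), params.intercept, dtype=float)

    def slope_for(c: str, base: float) -> float:
        # multiplicative trait scaling, clipped so the effect weakens
        # toward (but never flips past) zero at one end of the trait axis
        f_size = np.clip(1.0 + params.size_scaling.get(c, 0.0) * z_size, 0.1, 3.0)
        f_range = np.clip(1.0 - params.range_scaling.get(c, 0.0) * z_range, 0.1, 3.0)
        return base * f_size * f_range

    for c, base in params.linear_slopes.items():
        x = correlates[c].to_numpy(dtype=float)
        sd = x.std() or 1.0
        eta += slope_for(c, base) * (x - x.mean()) / sd
    for c, pw in params.piecewise.items():
        x = correlates[c].to_numpy(dtype=float)
        sd = x.std() or 1.0
        thr = pw.threshold + pw.threshold_shift * z_size
        before = np.minimum(x - thr, 0.0) / sd
        after = np.maximum(x - thr, 0.0) / sd
        eta += slope_for(c, pw.slope_before) * before + slope_for(c, pw.slope_after) * after
    return eta


def simulate_occurrence(
    traits: pd.DataFrame,
    correlates: pd.DataFrame,
    params: TrueModelParams,
    hulls: Mapping[str, RangeHull] | None = None,
    seed: int = 0,
) -> OccurrenceSim:
    """Draw the location x species presence/absence matrix.

    Occurrence probability is ``expit`` of the piecewise-linear logit in
    :func:`true_logit`; locations outside a species' range hull have
    probability exactly 0.  A hull overlapping no location triggers a
    warning and an all-absent column.
    """
    params.validate()
    rng = substream(seed, 4)
    n_loc = len(correlates)
    log_size = np.log(traits["body_size"].to_numpy(dtype=float))
    log_range = np.log(traits["range_size"].to_numpy(dtype=float))
    zs = (log_size - log_size.mean()) / max(log_size.std(), 1e-12)
    zr = (log_range - log_range.mean()) / max(log_range.std(), 1e-12)

    probs = np.zeros((n_loc, len(traits)))
    mask = np.ones((n_loc, len(traits)), dtype=bool)
    for j, (_, row) in enumerate(traits.iterrows()):
        eta = true_logit(row, correlates, params, zs[j], zr[j])
        p = expit(eta)
        if hulls is not None:
            m = within_range(correlates, hulls[row["species_id"]])
            if not m.any():
                warnings.warn(
                    f"range hull of {row['species_id']} overlaps no survey location; "
                    "species emitted as all-absent",
                    stacklevel=2,
                )
            p = np.where(m, p, 0.0)
            mask[:, j] = m
        probs[:, j] = p

    draws = (rng.random(probs.shape) < probs).astype(int)
    idx = correlates["location_id"]
    cols = traits["species_id"]
    return OccurrenceSim(
        matrix=pd.DataFrame(draws, index=idx, columns=cols),
        prob=pd.DataFrame(probs, index=idx, columns=cols),
        in_range=pd.DataFrame(mask, index=idx, columns=cols),
    )


# ---------------------------------------------------------------------------
# replicate-level surveys
# ---------------------------------------------------------------------------

SOURCES = ("RLS", "GASPAR", "WCS", "PROCFish")
_SOURCE_PROBS = (0.40, 0.30, 0.20, 0.10)
_SOURCE_AREAS = {"RLS": 500.0, "GASPAR": 250.0, "WCS": 154.0, "PROCFish": 100.0}

SURVEY_COLUMNS = [
    "location_id", "replicate_id", "transect_area", "data_source",
    "species_id", "detected", "distance_band", "fishing_intensity",
]


def detection_probability(traits: pd.DataFrame, params: TrueModelParams,
                          transect_area: float | np.ndarray) -> np.ndarray:
    """Per-replicate detection probability given presence, per species."""
    eta = (params.detect_intercept
           + params.detect_size_slope * traits["body_size"].to_numpy(dtype=float))
    for trait, offs in params.detect_offsets.items():
        lev = traits[trait].astype(str)
        eta = eta + lev.map(lambda v: offs.get(v, 0.0)).to_numpy(dtype=float)
    eta = eta + params.detect_area_coef * np.log(
        np.asarray(transect_area, dtype=float) / params.transect_area_ref
    )
    return expit(eta)


def simulate_surveys(
    occurrence,
    traits: pd.DataFrame,
    params: TrueModelParams,
    n_replicates: int = 4,
    seed: int = 0,
    correlates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Replicate-level survey records from the true occupancy matrix.

    At occupied cells each replicate detects the species with probability
    ``expit(detect_intercept + size slope * body size + behaviour offsets +
    detect_area_coef * log(area/area_ref))``; unoccupied cells never yield
    detections.  Detections fall in the beyond-5m band only (a false
    absence within 5 m) with the avoidance probability, optionally growing
    with fishing intensity.  Fishing intensity (ordinal 1-5) is the
    human-impact quintile when ``correlates`` is given, else uniform.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    matrix = occurrence.matrix if isinstance(occurrence, OccurrenceSim) else occurrence
    params.validate()
    rng = substream(seed, 5)

    loc_ids = matrix.index.to_numpy()
    sp_ids = matrix.columns.to_numpy()
    n_loc, n_sp = matrix.shape

    source = rng.choice(SOURCES, size=n_loc, p=_SOURCE_PROBS)
    area = np.array([_SOURCE_AREAS[s] for s in source])
    if area.size and (area <= 0).any():
        raise ValueError("transect_area must be positive")
    if correlates is not None:
        hi = correlates.set_index("location_id").loc[loc_ids, "human_impact"].to_numpy()
        fishing = (pd.qcut(pd.Series(hi), 5, labels=False, duplicates="drop").to_numpy() + 1)
    else:
        fishing = rng.integers(1, 6, size=n_loc)

    t = traits.set_index("species_id").loc[sp_ids].reset_index()
    p_det = np.vstack([detection_probability(t, params, a) for a in area])  # n_loc x n_sp

    occ = matrix.to_numpy()
    rows = []
    for r in range(n_replicates):
        det = (rng.random((n_loc, n_sp)) < p_det) & (occ == 1)
        p_avoid = np.clip(
            params.avoidance_base
            + params.avoidance_fishing_effect * (fishing - 1)[:, None], 0.0, 1.0)
        beyond = det & (rng.random((n_loc, n_sp)) < p_avoid)
        band = np.where(det, np.where(beyond, "beyond-5m", "within-5m"), None)
        rows.append(pd.DataFrame({
            "location_id": np.repeat(loc_ids, n_sp),
            "replicate_id": f"R{r + 1}",
            "transect_area": np.repeat(area, n_sp),
            "data_source": np.repeat(source, n_sp),
            "species_id": np.tile(sp_ids, n_loc),
            "detected": det.ravel().astype("float"),
            "distance_band": band.ravel(),
            "fishing_intensity": np.repeat(fishing, n_sp),
        }))
    survey = pd.concat(rows, ignore_index=True)
    survey["detected"] = survey["detected"].astype("Float64")
    return survey.sort_values(["location_id", "replicate_id", "species_id"],
                              ignore_index=True)


def pooled_presence(survey: pd.DataFrame) -> pd.DataFrame:
    """Location x species pooled matrix: 1 iff any replicate detection,
    0 if surveyed and never detected, NA if every record is NA."""
    piv = survey.pivot_table(index="location_id", columns="species_id",
                             values="detected", aggfunc="max", dropna=False)
    return piv.astype("Float64")


def make_restricted_lists(
    survey: pd.DataFrame,
    traits: pd.DataFrame,
    sources: Sequence[str] = ("WCS", "PROCFish"),
    target_fraction: float = 0.08,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Choose per-source restricted species lists so that blanking them out
    yields an overall NA fraction close to ``target_fraction``.

    Each listed source gets the same restricted *fraction* f of species,
    solved from ``f * (share of records in listed sources) = target``.
    """
    rng = substream(seed, 6)
    shares = survey["data_source"].value_counts(normalize=True)
    covered = float(shares.reindex(sources).fillna(0.0).sum())
    if covered == 0:
        return {s: [] for s in sources}
    f = min(target_fraction / covered, 1.0)
    sp = traits["species_id"].to_numpy()
    out = {}
    for s in sources:
        k = int(round(f * len(sp)))
        out[s] = sorted(rng.choice(sp, size=k, replace=False).tolist())
    return out


def apply_missingness(
    survey: pd.DataFrame,
    restricted_lists: Mapping[str, Sequence[str]],
    seed: int = 0,
) -> pd.DataFrame:
    """Blank out records of restricted (source, species) pairs as NA.

    NA means "not surveyed", never "absent".  The returned frame carries the
    overall NA fraction in ``.attrs['na_fraction']``.  Deterministic: the
    seed parameter is accepted for interface symmetry but unused.
    """
    known_sources = set(survey["data_source"].unique())
    known_species = set(survey["species_id"].unique())
    for src, spp in restricted_lists.items():
        if src not in known_sources:
            raise ValueError(f"unknown data source in restricted list: {src!r}")
        unknown = set(spp) - known_species
        if unknown:
            raise ValueError(f"unknown species in restricted list for {src!r}: {sorted(unknown)[:5]}")
    out = survey.copy()
    blank = np.zeros(len(out), dtype=bool)
    for src, spp in restricted_lists.items():
        blank |= (out["data_source"].to_numpy() == src) & out["species_id"].isin(spp).to_numpy()
    out.loc[blank, "detected"] = pd.NA
    out.loc[blank, "distance_band"] = None
    out.attrs["na_fraction"] = float(blank.mean()) if len(out) else 0.0
    return out
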