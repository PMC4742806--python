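"""Second-level inference: traits vs occurrence-model outputs.

The per-species BRT outputs (total CV deviance explained and per-correlate
contributions) are aggregated to the four competing hypotheses
(biogeography, area, energy, human pressure) and modelled as functions of
species traits with genus-in-family random intercepts — a taxonomic proxy
for phylogenetic non-independence.  Model sets are built in two stages
(each trait alone vs the intercept-only null; survivors, their pairs, and
pairs with interaction), ranked by small-sample AICc, and predictions are
model-averaged with wAICc weights over a body-size x range-size grid.

Gaussian-with-log-link responses are realized as Gaussian mixed models on
``log(y + eps)`` (eps = 0.1 percentage points by default) because zero
contributions make a pure log link undefined; the transform is recorded on
every fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .synthetic import HYPOTHESES, HYPOTHESIS_MAP

__all__ = [
    "aicc",
    "waicc",
    "aggregate_contributions",
    "make_trait_data",
    "TraitModelFit",
    "fit_trait_model",
    "model_set_formulas",
    "build_model_set",
    "ModelSet",
    "model_average",
    "prediction_grid",
    "range_vs_size",
    "RESPONSES",
]

RESPONSES = ("total_deviance_explained",) + HYPOTHESES


# ---------------------------------------------------------------------------
# information criteria
# ---------------------------------------------------------------------------

def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion corrected for small samples:
    ``-2 loglik + 2k + 2k(k+1)/(n-k-1)``.

    Raises
    ------
    ValueError
        If ``n <= k + 1`` (the correction term is undefined).
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def waicc(aicc_values) -> np.ndarray:
    """Akaike weights: ``w_i = exp(-d_i/2) / sum_j exp(-d_j/2)`` with
    ``d_i = AICc_i - min AICc``.  Invariant to adding a constant to every
    log-likelihood; always sums to 1."""
    a = np.asarray(aicc_values, dtype=float)
    d = a - np.nanmin(a)
    w = np.exp(-d / 2.0)
    w[np.isnan(w)] = 0.0
    return w / w.sum()


# ---------------------------------------------------------------------------
# hypothesis aggregation
# ---------------------------------------------------------------------------

def aggregate_contributions(
    brt_results,
    hypothesis_map: Mapping[str, str] = HYPOTHESIS_MAP,
) -> pd.DataFrame:
    """Sum per-correlate BRT contributions within each hypothesis family.

    One row per converged species with the four hypothesis percentages
    (summing to 100), the total CV deviance explained, and the "absolute"
    variant (hypothesis share x total deviance / 100) for analyses on the
    deviance scale.  Non-converged species are excluded.

    Raises
    ------
    KeyError
        If a correlate in the results is missing from the hypothesis map.
    """
    rows = []
    for r in brt_results:
        if not getattr(r, "converged", False) or r.contributions is None:
            continue
        unmapped = [c for c in r.contributions.index if c not in hypothesis_map]
        if unmapped:
            raise KeyError(f"correlates not mapped to a hypothesis: {unmapped}")
        sums = {h: 0.0 for h in HYPOTHESES}
        for c, v in r.contributions.items():
            sums[hypothesis_map[c]] += v
        row = {"species_id": r.species_id,
               "total_deviance_explained": r.cv_deviance_explained, **sums}
        for h in HYPOTHESES:
            row[f"abs_{h}"] = sums[h] * r.cv_deviance_explained / 100.0
        rows.append(row)
    cols = ["species_id", "total_deviance_explained", *HYPOTHESES,
            *[f"abs_{h}" for h in HYPOTHESES]]
    return pd.DataFrame(rows, columns=cols)


def make_trait_data(hyp_contrib: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Join hypothesis contributions to traits and add the derived
    predictors used in the trait models (log body size, log range size)."""
    df = hyp_contrib.merge(traits, on="species_id", how="inner", validate="one_to_one")
    df["log_body_size"] = np.log(df["body_size"])
    df["log_range_size"] = np.log(df["range_size"])
    return df


# ---------------------------------------------------------------------------
# Gaussian mixed model on the log scale
# ---------------------------------------------------------------------------

@dataclass
class TraitModelFit:
    """A trait-level mixed-model fit.

    The response is modelled as ``log(y + epsilon) ~ formula`` with random
    intercepts for family and genus-within-family (additive terms); k
    counts fixed effects + variance components + the residual variance.
    """

    response: str
    formula: str
    params: pd.Series
    bse: pd.Series
    loglik: float
    k: int
    n: int
    aicc: float
    r2_marginal: float
    r2_conditional: float
    vc: dict[str, float]
    epsilon: float
    waicc: float | None = None
    degraded: bool = False
    _design_info: object = field(default=None, repr=False)

    def predict(self, newdata: pd.DataFrame, response_scale: bool = True) -> np.ndarray:
        """Population-level (fixed-effects) prediction; on the response
        scale this back-transforms ``exp(eta) - epsilon``."""
        from patsy import build_design_matrices
        (X,) = build_design_matrices([self._design_info], newdata)
        eta = np.asarray(X) @ self.params.to_numpy()
        return np.exp(eta) - self.epsilon if response_scale else eta

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm
        z = norm.ppf(1 - alpha / 2)
        return pd.DataFrame({"lower": self.params - z * self.bse,
                             "upper": self.params + z * self.bse})


def fit_trait_model(
    data: pd.DataFrame,
    formula: str,
    response: str,
    epsilon: float = 0.1,
) -> TraitModelFit:
    """Fit one trait model by maximum likelihood.

    ``formula`` is the fixed-effect right-hand side (``"1"`` for the null
    model).  Requires >= 2 families; singular variance components trigger a
    refit without the failing component (flagged ``degraded``).
    """
    df = data.dropna(subset=[response]).copy()
    if df["family"].nunique() < 2:
        raise ValueError("need >= 2 families for the nested random effects")
    y = df[response].to_numpy(dtype=float)
    if (y + epsilon <= 0).any():
        # responses like null-model deviance explained can dip slightly
        # below zero; shift the offset just enough and record it
        epsilon = float(-y.min() + max(epsilon, 0.1))
    df["_z"] = np.log(y + epsilon)

    def _fit(vc: bool):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if vc:
                md = smf.mixedlm(f"_z ~ {formula}", df, groups=df["family"],
                                 re_formula="1", vc_formula={"genus": "0 + C(genus)"})
            else:
                md = smf.mixedlm(f"_z ~ {formula}", df, groups=df["family"],
                                 re_formula="1")
            return md.fit(reml=False, method="lbfgs", maxiter=500)

    degraded = False
    res = None
    for vc in (True, False):
        try:
            cand = _fit(vc=vc)
            if np.isfinite(cand.llf):
                res = cand
                degraded = not vc
                break
        except Exception:
            continue
    if res is None:
        # last resort at very small n: plain OLS on the transformed scale,
        # flagged as degraded (no random-effect structure)
        import statsmodels.formula.api as _smf
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ols = _smf.ols(f"_z ~ {formula}", df).fit()
        p = len(ols.params)
        k = p + 1
        var_fixed = float(np.var(ols.fittedvalues))
        var_resid = float(ols.scale)
        denom = var_fixed + var_resid
        return TraitModelFit(
            response=response, formula=formula,
            params=ols.params, bse=ols.bse,
            loglik=float(ols.llf), k=k, n=len(df),
            aicc=aicc(float(ols.llf), k, len(df)),
            r2_marginal=var_fixed / denom,
            r2_conditional=var_fixed / denom,
            vc={"family": 0.0, "genus": 0.0, "residual": var_resid},
            epsilon=epsilon, degraded=True,
            _design_info=ols.model.data.design_info,
        )

    with warnings.catch_warnings():
        # boundary variance estimates make some covariance entries NaN;
        # the fixed-effect block we use is fine
        warnings.simplefilter("ignore", RuntimeWarning)
        fe = res.fe_params
        bse_fe = res.bse_fe
    p = len(fe)
    var_family = float(np.asarray(res.cov_re)[0, 0]) if res.cov_re is not None else 0.0
    var_genus = float(res.vcomp[0]) if (not degraded and len(res.vcomp)) else 0.0
    var_resid = float(res.scale)
    exog = res.model.exog
    var_fixed = float(np.var(exog @ fe.to_numpy()))
    denom = var_fixed + var_family + var_genus + var_resid
    n = len(df)
    k = p + (1 if degraded else 2) + 1
    return TraitModelFit(
        response=response,
        formula=formula,
        params=fe,
        bse=bse_fe,
        loglik=float(res.llf),
        k=k,
        n=n,
        aicc=aicc(float(res.llf), k, n),
        r2_marginal=var_fixed / denom,
        r2_conditional=(var_fixed + var_family + var_genus) / denom,
        vc={"family": var_family, "genus": var_genus, "residual": var_resid},
        epsilon=epsilon,
        degraded=degraded,
        _design_info=res.model.data.design_info,
    )


# ---------------------------------------------------------------------------
# model sets
# ---------------------------------------------------------------------------

def model_set_formulas(survivors: Sequence[str]) -> list[str]:
    """Final model-set formulas from the stage-1 survivors: the retained
    single-trait models, all their pairwise additive combinations, the
    pairs with interaction, and the null (always carried for reference)."""
    formulas = ["1"] + list(survivors)
    surv = list(survivors)
    for i in range(len(surv)):
        for j in range(i + 1, len(surv)):
            formulas.append(f"{surv[i]} + {surv[j]}")
            formulas.append(f"{surv[i]} * {surv[j]}")
    return formulas


@dataclass
class ModelSet:
    """A fitted AICc model set for one response variable."""

    response: str
    fits: dict[str, TraitModelFit]
    survivors: list[str]
    null_only: bool

    @property
    def table(self) -> pd.DataFrame:
        a = np.array([f.aicc for f in self.fits.values()])
        rows = pd.DataFrame({
            "formula": list(self.fits),
            "k": [f.k for f in self.fits.values()],
            "loglik": [f.loglik for f in self.fits.values()],
            "AICc": a,
            "dAICc": a - a.min(),
            "wAICc": [f.waicc for f in self.fits.values()],
            "R2_marginal": [f.r2_marginal for f in self.fits.values()],
            "R2_conditional": [f.r2_conditional for f in self.fits.values()],
        })
        return rows.sort_values("AICc", ignore_index=True)

    @property
    def best_formula(self) -> str:
        return max(self.fits, key=lambda f: self.fits[f].waicc or 0.0)


def build_model_set(
    data: pd.DataFrame,
    response: str,
    candidates: Sequence[str],
    epsilon: float = 0.1,
) -> ModelSet:
    """Two-stage AICc model-set construction for one response.

    Stage 1 fits each candidate trait alone plus the intercept-only null;
    traits whose wAICc beats the null's are retained.  Stage 2 fits the
    retained singles, their pairs with and without interaction, and the
    null; wAICc is renormalized within the final set.  If nothing beats
    the null the final set is just the null, flagged.
    """
    stage1 = {"1": fit_trait_model(data, "1", response, epsilon)}
    for c in candidates:
        try:
            stage1[c] = fit_trait_model(data, c, response, epsilon)
        except Exception as exc:  # unusable candidate (e.g. constant column)
            warnings.warn(f"candidate {c!r} failed for {response}: {exc}", stacklevel=2)
    w1 = waicc([f.aicc for f in stage1.values()])
    labels = list(stage1)
    w_null = w1[labels.index("1")]
    survivors = [c for c, w in zip(labels, w1) if c != "1" and w > w_null]

    formulas = model_set_formulas(survivors)
    fits: dict[str, TraitModelFit] = {}
    for f in formulas:
        fits[f] = stage1[f] if f in stage1 else fit_trait_model(data, f, response, epsilon)
    w = waicc([fits[f].aicc for f in formulas])
    for f, wi in zip(formulas, w):
        fits[f].waicc = float(wi)
    return ModelSet(response=response, fits=fits, survivors=survivors,
                    null_only=(len(survivors) == 0))


# ---------------------------------------------------------------------------
# model averaging
# ---------------------------------------------------------------------------

def prediction_grid(data: pd.DataFrame, n: int = 50) -> pd.DataFrame:
    """Body-size x range-size grid over the observed trait ranges (body size
    log-spaced), with categorical predictors at their modal level."""
    bs = np.exp(np.linspace(data["log_body_size"].min(), data["log_body_size"].max(), n))
    rs = np.linspace(data["range_size"].min(), data["range_size"].max(), n)
    g = pd.DataFrame([(b, r) for b in bs for r in rs], columns=["body_size", "range_size"])
    g["log_body_size"] = np.log(g["body_size"])
    g["log_range_size"] = np.log(g["range_size"])
    for c in data.columns:
        if data[c].dtype == object and c not in g:
            g[c] = data[c].mode().iloc[0]
    return g


def model_average(
    model_set: ModelSet | Mapping[str, TraitModelFit],
    newdata: pd.DataFrame,
    weights: Sequence[float] | None = None,
) -> np.ndarray:
    """wAICc-weighted average of member-model predictions at ``newdata``.

    Weights not summing to 1 are renormalized with a warning.  The average
    is pointwise, so it always lies within the member-prediction envelope.
    """
    fits = list(model_set.fits.values()) if isinstance(model_set, ModelSet) \
        else list(model_set.values())
    if weights is None:
        weights = [f.waicc if f.waicc is not None else np.nan for f in fits]
    w = np.asarray(weights, dtype=float)
    if np.isnan(w).any():
        raise ValueError("missing weights: fit the model set first")
    total = w.sum()
    if not np.isclose(total, 1.0):
        warnings.warn(f"weights sum to {total:.6f}; renormalizing", stacklevel=2)
        w = w / total
    preds = np.vstack([f.predict(newdata) for f in fits])
    return w @ preds


def range_vs_size(traits: pd.DataFrame, epsilon: float = 0.0) -> TraitModelFit:
    """Geographic range size as a function of body size (log-link Gaussian
    mixed model with the same genus-in-family random structure)."""
    df = traits.copy()
    df["log_body_size"] = np.log(df["body_size"])
    return fit_trait_model(df, "log_body_size", "range_size", epsilon=epsilon)
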