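"""Critical thresholds in class-averaged partial effects.

Per-species partial-dependence curves are averaged within body-size
classes (<=15, 16-50, >50 cm), optionally restricted to the small-ranging
subset (first quartile of range sizes, truncated to the 98th percentile of
the correlate values where those species occur).  Each mean curve is then
tested for a change in slope at an unknown breakpoint with the Davies
test; where significant (p < 0.05), the breakpoint T is estimated by
segmented linear regression (iterative linearization), and the before/
after slopes are reported with the x axis rescaled to [0, 1] so rates of
change are comparable across correlates with different units.

The drop between the pre-threshold occurrence plateau and the
post-threshold level is summarised by ``percent_reduction``:
``100 * (1 - p_low / p_ref)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import HYPOTHESIS_MAP, SIZE_CLASSES, size_class, small_ranging_flag, substream

__all__ = [
    "MeanPartialEffect",
    "mean_partial_effect",
    "davies_test",
    "BreakpointFit",
    "fit_segmented",
    "rate_of_change",
    "percent_reduction",
    "threshold_table",
    "CORRELATE_UNITS",
]

CORRELATE_UNITS = {
    "dist_to_land": "km",
    "reef_area_50km": "km^2",
    "sst_sdev": "degC",
    "human_impact": "-",
}


# ---------------------------------------------------------------------------
# class-averaged partial effects
# ---------------------------------------------------------------------------

@dataclass
class MeanPartialEffect:
    """Mean partial effect across the species of one group."""

    group: str
    correlate: str
    small_ranging: bool
    x: np.ndarray
    mean: np.ndarray        # on `scale`
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_species: int
    scale: str              # "prob" or "logit"
    ci_method: str

    @property
    def empty(self) -> bool:
        return self.n_species == 0


def _curves_for(curves: pd.DataFrame, correlate: str, species: list[str]) -> dict[str, pd.DataFrame]:
    sub = curves[(curves["correlate"] == correlate) & curves["species_id"].isin(species)]
    return {sp: g.sort_values("x") for sp, g in sub.groupby("species_id")}


def mean_partial_effect(
    curves: pd.DataFrame,
    traits: pd.DataFrame,
    group: str,
    correlate: str,
    small_ranging: bool = False,
    within_class_quartile: bool = True,
    scale: str = "prob",
    n_grid: int = 100,
    ci: str = "auto",
    n_boot: int = 1000,
    seed: int = 0,
) -> MeanPartialEffect:
    """Average per-species partial-dependence curves within a size class.

    Curves (long format: species_id, correlate, x, logit, prob) are
    interpolated onto a common grid spanning the pooled x range, then
    averaged pointwise with a 95% CI across species.  ``ci`` is
    ``"normal"`` (mean +- 1.96 se), ``"bootstrap"`` (percentile over
    species resamples) or ``"auto"`` (bootstrap when fewer than 30
    species).  The small-ranging subset (first quartile of range sizes)
    is truncated at the 98th percentile of its pooled correlate values.
    Groups with fewer than 2 species give an explicit empty result.
    """
    if group not in SIZE_CLASSES:
        raise ValueError(f"group must be one of {SIZE_CLASSES}")
    if scale not in ("prob", "logit"):
        raise ValueError("scale must be 'prob' or 'logit'")
    cls = pd.Series(size_class(traits["body_size"]), index=traits.index)
    sel = traits[cls == group]
    if small_ranging:
        flag = small_ranging_flag(traits, within_class=within_class_quartile)
        sel = sel[flag.loc[sel.index]]
    sp_curves = _curves_for(curves, correlate, list(sel["species_id"]))
    n_sp = len(sp_curves)
    if n_sp < 2:
        z = np.empty(0)
        return MeanPartialEffect(group, correlate, small_ranging, z, z, z, z,
                                 n_species=n_sp, scale=scale, ci_method="none")

    xs = np.concatenate([c["x"].to_numpy() for c in sp_curves.values()])
    hi = np.percentile(xs, 98.0) if small_ranging else xs.max()
    grid = np.linspace(xs.min(), hi, n_grid)
    Y = np.vstack([
        np.interp(grid, c["x"].to_numpy(), c[scale].to_numpy())
        for c in sp_curves.values()
    ])
    mean = Y.mean(axis=0)

    method = ci
    if ci == "auto":
        method = "bootstrap" if n_sp < 30 else "normal"
    if method == "normal":
        se = Y.std(axis=0, ddof=1) / np.sqrt(n_sp)
        lo, hi_ci = mean - 1.96 * se, mean + 1.96 * se
    elif method == "bootstrap":
        rng = substream(seed, 12)
        idx = rng.integers(0, n_sp, size=(n_boot, n_sp))
        boots = Y[idx].mean(axis=1)
        lo, hi_ci = np.percentile(boots, [2.5, 97.5], axis=0)
        # pointwise percentile intervals can exclude the mean only by
        # floating pathology; clamp so lower <= mean <= upper holds
        lo, hi_ci = np.minimum(lo, mean), np.maximum(hi_ci, mean)
    else:
        raise ValueError("ci must be 'auto', 'normal' or 'bootstrap'")
    return MeanPartialEffect(group, correlate, small_ranging, grid, mean, lo, hi_ci,
                             n_species=n_sp, scale=scale, ci_method=method)


# ---------------------------------------------------------------------------
# Davies test
# ---------------------------------------------------------------------------

def _hinge_tstats(x: np.ndarray, y: np.ndarray, psis: np.ndarray) -> np.ndarray:
    """Signed t statistics of the hinge coefficient at each candidate
    breakpoint, under the linear null design ``y ~ 1 + x + (x - psi)_+``."""
    n = len(x)
    ts = np.full(len(psis), np.nan)
    for i, psi in enumerate(psis):
        h = np.maximum(x - psi, 0.0)
        X = np.column_stack([np.ones(n), x, h])
        XtX = X.T @ X
        try:
            XtX_inv = np.linalg.inv(XtX)
        except np.linalg.LinAlgError:
            continue
        beta = XtX_inv @ (X.T @ y)
        resid = y - X @ beta
        dof = n - 3
        s2 = resid @ resid / dof
        se = np.sqrt(max(s2 * XtX_inv[2, 2], 0.0))
        if se > 0:
            ts[i] = beta[2] / se
    return ts


def davies_test(x, y, k: int = 10, full: bool = False):
    """Davies test for a slope change at an unknown breakpoint.

    The hinge-term score is evaluated at ``k`` candidate breakpoints on an
    even grid over the central 90% of x; the p-value is the Davies upper
    bound on the maximum of the correlated two-sided t process:
    ``p = 2 Phi(-M) + V exp(-M^2/2) / sqrt(8 pi)`` with M the largest
    |t| and V the total variation of the t process.  The bound is
    conservative by construction.  Constant y returns p = 1 by convention.

    With ``full=True``, returns ``(p, best_psi)`` where ``best_psi`` is the
    candidate with the largest |t| (a natural segmented-fit start).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 10:
        raise ValueError("davies_test needs at least 10 points")
    order = np.argsort(x)
    x, y = x[order], y[order]
    if not np.all(np.diff(x) > 0):
        raise ValueError("x must be strictly increasing (no ties)")
    if np.ptp(y) == 0:
        return (1.0, float(np.median(x))) if full else 1.0

    lo, hi = np.quantile(x, [0.05, 0.95])
    psis = np.linspace(lo, hi, k)
    ts = _hinge_tstats(x, y, psis)
    valid = np.isfinite(ts)
    if not valid.any():
        return (1.0, float(np.median(x))) if full else 1.0
    ts_v = ts[valid]
    M = float(np.max(np.abs(ts_v)))
    V = float(np.sum(np.abs(np.diff(ts_v))))
    # two-sided Davies bound on the max of the correlated t process; the
    # t tail (rather than normal) keeps the bound conservative at small n
    from scipy.stats import t as t_dist
    p = 2.0 * (t_dist.sf(M, len(x) - 3)
               + V * np.exp(-(M**2) / 2.0) / np.sqrt(8.0 * np.pi))
    p = float(min(1.0, p))
    if full:
        best = psis[valid][int(np.argmax(np.abs(ts_v)))]
        return p, float(best)
    return p


# ---------------------------------------------------------------------------
# segmented regression
# ---------------------------------------------------------------------------

@dataclass
class BreakpointFit:
    """Estimated breakpoint of a piecewise-linear relationship."""

    correlate: str
    group: str
    psi: float
    psi_se: float
    davies_p: float
    slope_before: float         # per x unit
    slope_after: float
    rescaled_before: float      # slope with x rescaled to [0, 1]
    rescaled_after: float
    converged: bool
    n_iter: int = 0
    se_method: str = "delta"


def _profile_rss_psi(x: np.ndarray, y: np.ndarray, n_cand: int = 100) -> float:
    """Global profile search: the candidate breakpoint (interior 5-95% of
    x) minimizing the residual sum of squares of the broken-line fit."""
    lo, hi = np.quantile(x, [0.05, 0.95])
    cands = np.linspace(lo, hi, n_cand)
    best_psi, best_rss = float(cands[0]), np.inf
    ones = np.ones_like(x)
    for psi in cands:
        X = np.column_stack([ones, x, np.maximum(x - psi, 0.0)])
        beta, rss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        rss = float(r @ r)
        if rss < best_rss:
            best_rss, best_psi = rss, float(psi)
    return best_psi


def fit_segmented(
    x,
    y,
    psi0: float | None = None,
    correlate: str = "",
    group: str = "",
    davies_p: float = np.nan,
    max_iter: int = 100,
) -> BreakpointFit:
    """Segmented (broken-line) regression with one breakpoint.

    Iterative linearization: refit ``y ~ 1 + x + (x - psi)_+ + V`` with
    ``V = -1(x > psi)``, update ``psi`` by the ratio of the V coefficient
    to the hinge coefficient, until |d psi| < 1e-6 * range(x) or
    ``max_iter``.  ``psi0=None`` starts from a global profile-RSS search
    over interior candidates (recommended: the iteration alone can settle
    in a local solution).  The s.e. of psi comes from the delta method
    (the leading term ``se(gamma)/|beta_hinge|`` at convergence, where the
    V coefficient gamma is ~0).  Breakpoints escaping the interior of x or
    failing to settle are returned with ``converged=False`` at the last
    iterate — degenerate slope changes surface as non-convergence or an
    s.e. spanning a large share of the range, never as a silent answer.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    rng_x = float(np.ptp(x))
    if rng_x <= 0:
        raise ValueError("x has zero range")
    lo, hi = float(x.min()), float(x.max())
    if psi0 is None:
        psi0 = _profile_rss_psi(x, y)
    psi = float(np.clip(psi0, lo + 1e-9 * rng_x, hi - 1e-9 * rng_x))
    tol = 1e-6 * rng_x

    converged = False
    escaped = False
    beta = None
    cov = None
    it = 0
    damp = 1.0
    prev_step = None
    for it in range(1, max_iter + 1):
        U = np.maximum(x - psi, 0.0)
        V = -(x > psi).astype(float)
        X = np.column_stack([np.ones_like(x), x, U, V])
        XtX = X.T @ X
        try:
            XtX_inv = np.linalg.inv(XtX)
        except np.linalg.LinAlgError:
            break
        beta = XtX_inv @ (X.T @ y)
        resid = y - X @ beta
        dof = max(len(x) - 4, 1)
        s2 = float(resid @ resid) / dof
        cov = s2 * XtX_inv
        b_u, gamma = beta[2], beta[3]
        if abs(b_u) < 1e-12:
            break
        step = gamma / b_u
        # the update oscillates once psi is between two data points: the
        # design changes discretely with psi, so damp on sign reversals
        if prev_step is not None and step * prev_step < 0:
            damp *= 0.5
        prev_step = step
        psi_new = psi + damp * step
        if not (lo < psi_new < hi):
            psi = float(np.clip(psi_new, lo + 1e-9 * rng_x, hi - 1e-9 * rng_x))
            escaped = True
            break
        psi = psi_new
        if abs(damp * step) < tol:
            converged = True
            break
    else:
        # max_iter reached: accept if the update settled below the grid
        # resolution (psi is only identified up to the inter-point gap)
        if prev_step is not None and abs(damp * prev_step) < 1e-3 * rng_x:
            converged = True

    if beta is None:
        return BreakpointFit(correlate, group, psi, np.inf, davies_p,
                             np.nan, np.nan, np.nan, np.nan, converged=False, n_iter=it)
    b_x, b_u, gamma = beta[1], beta[2], beta[3]
    if abs(b_u) > 1e-12 and cov is not None:
        r = gamma / b_u
        var_psi = (cov[3, 3] - 2 * r * cov[2, 3] + r**2 * cov[2, 2]) / b_u**2
        psi_se = float(np.sqrt(max(var_psi, 0.0)))
    else:
        psi_se = np.inf
    # identifiability guards: a credible breakpoint sits in the interior
    # 5-95% of x (edge kinks are artifacts) and carries a slope change
    # clearly larger than its standard error
    q05, q95 = np.quantile(x, [0.05, 0.95])
    interior = q05 <= psi <= q95
    se_bu = float(np.sqrt(max(cov[2, 2], 0.0))) if cov is not None else np.inf
    identifiable = np.isfinite(se_bu) and se_bu > 0 and abs(b_u) > 2.0 * se_bu
    return BreakpointFit(
        correlate=correlate, group=group,
        psi=float(psi), psi_se=psi_se, davies_p=davies_p,
        slope_before=float(b_x), slope_after=float(b_x + b_u),
        rescaled_before=float(b_x * rng_x),
        rescaled_after=float((b_x + b_u) * rng_x),
        converged=converged and not escaped and interior and identifiable,
        n_iter=it,
    )


def rate_of_change(fit: BreakpointFit, x_range: tuple[float, float]) -> tuple[float, float]:
    """Before/after slopes with x rescaled to [0, 1]: slope * (x_max - x_min)."""
    width = float(x_range[1]) - float(x_range[0])
    if width <= 0:
        raise ValueError("x_range has zero width")
    return fit.slope_before * width, fit.slope_after * width


def percent_reduction(p_ref: float, p_low: float) -> float:
    """Percent reduction from a reference occurrence probability:
    ``100 * (1 - p_low / p_ref)``."""
    if not (0 < p_ref <= 1):
        raise ValueError("p_ref must be in (0, 1]")
    if p_low < 0:
        raise ValueError("p_low must be >= 0")
    if p_low > p_ref:
        raise ValueError("p_low exceeds p_ref: reduction would be negative "
                         "(check the argument order)")
    return 100.0 * (1.0 - p_low / p_ref)


# ---------------------------------------------------------------------------
# Table-1-style threshold table
# ---------------------------------------------------------------------------

def bootstrap_threshold_se(
    curves: pd.DataFrame,
    traits: pd.DataFrame,
    group: str,
    correlate: str,
    psi0: float,
    small_ranging: bool = False,
    n_boot: int = 200,
    seed: int = 0,
    **mpe_kwargs,
) -> float:
    """Bootstrap alternative to the delta-method s.e. of a threshold:
    resample species, rebuild the mean curve, refit the segmented model,
    and return the s.d. of the converged breakpoint estimates."""
    rng = substream(seed, 13)
    cls = pd.Series(size_class(traits["body_size"]), index=traits.index)
    sel = traits[cls == group]
    if small_ranging:
        flag = small_ranging_flag(traits)
        sel = sel[flag.loc[sel.index]]
    sp = list(sel["species_id"])
    psis = []
    for _ in range(n_boot):
        resample = [sp[i] for i in rng.integers(0, len(sp), size=len(sp))]
        sub = pd.concat([
            curves[(curves["species_id"] == s) & (curves["correlate"] == correlate)]
            .assign(species_id=f"{s}#{i}")
            for i, s in enumerate(resample)
        ], ignore_index=True)
        t_sub = pd.concat([
            traits[traits["species_id"] == s].assign(species_id=f"{s}#{i}")
            for i, s in enumerate(resample)
        ], ignore_index=True)
        eff = mean_partial_effect(sub, t_sub, group, correlate,
                                  small_ranging=False, ci="normal", **mpe_kwargs)
        if eff.empty:
            continue
        fit = fit_segmented(eff.x, eff.mean, psi0=psi0)
        if fit.converged:
            psis.append(fit.psi)
    return float(np.std(psis, ddof=1)) if len(psis) > 1 else np.inf


def threshold_table(
    mean_effects: list[MeanPartialEffect],
    alpha: float = 0.05,
    davies_k: int = 10,
) -> pd.DataFrame:
    """Threshold summary across size classes and correlates.

    One row per mean partial effect: the hypothesis family, correlate and
    unit, the Davies p, and — only where p < alpha and the segmented fit
    converged — the threshold T +- s.e. and the before/after rates of
    change on [0, 1]-rescaled x.  Non-significant rows carry NA
    thresholds.
    """
    rows = []
    for eff in mean_effects:
        row = {
            "group": eff.group,
            "small_ranging": eff.small_ranging,
            "hypothesis": HYPOTHESIS_MAP.get(eff.correlate, ""),
            "correlate": eff.correlate,
            "unit": CORRELATE_UNITS.get(eff.correlate, ""),
            "n_species": eff.n_species,
            "davies_p": np.nan,
            "threshold": np.nan,
            "threshold_se": np.nan,
            "rate_before": np.nan,
            "rate_after": np.nan,
            "converged": False,
        }
        if not eff.empty and len(eff.x) >= 10:
            p, best = davies_test(eff.x, eff.mean, k=davies_k, full=True)
            row["davies_p"] = p
            if p < alpha:
                fit = fit_segmented(eff.x, eff.mean, psi0=best,
                                    correlate=eff.correlate, group=eff.group,
                                    davies_p=p)
                row["converged"] = fit.converged
                if fit.converged:
                    row["threshold"] = fit.psi
                    row["threshold_se"] = fit.psi_se
                    row["rate_before"] = fit.rescaled_before
                    row["rate_after"] = fit.rescaled_after
        rows.append(row)
    cols = ["group", "small_ranging", "hypothesis", "correlate", "unit", "n_species",
            "davies_p", "threshold", "threshold_se", "rate_before", "rate_after",
            "converged"]
    return pd.DataFrame(rows, columns=cols)
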