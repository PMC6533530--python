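"""The two greenhouse analyses: log-SDW and colonization models.

Shoot dry weight is modeled on the natural-log scale with fixed effects for
run, treatment, edge/exterior position and the neighbor-mean SDW (with a
treatment-specific slope), random intercepts for subgroup, variety nested in
subgroup and a treatment-by-variety interaction, and a bivariate spline
field whose scope (one common field, one per box, or one per treatment
block) is chosen by BIC.  Hyphal colonization (AM blocks only) is modeled on
the percent scale with focal- and neighbor-SDW slopes, variety-in-subgroup
random intercepts and a Markov-random-field smoother over the planting
lattice, one field per block.

Spatial correction subtracts the fitted nuisance components (run, position,
neighbor and field effects, each centered so the raw scale is preserved)
from the observations, leaving treatment and genotype contributions intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import geometry, pmm

__all__ = [
    "SDWModelConfig", "HCModelConfig", "CorrectionResult",
    "SDWFit", "HCFit",
    "prepare_sdw_table", "prepare_hc_table",
    "fit_sdw_model", "select_spatial_structure", "fit_hc_model",
    "compare_additive_interactive", "spatially_correct",
    "lattice_adjacency",
]

_SCOPES = ("common", "per_box", "per_block")


@dataclass
class SDWModelConfig:
    scope: str = "common"               # spatial-trend scope
    spline_k: int = 8                   # marginal basis size
    include_neighbor: bool = True       # neighbor-mean SDW covariate
    include_gxt: bool = True            # treatment-by-variety random effect
    all_interactions: bool = False      # all pairwise fixed interactions
    select_fixed: bool = False          # backward p-value pruning of extras
    p_drop: float = 0.05
    optimizer: Optional[dict] = None

    def __post_init__(self):
        if self.scope not in _SCOPES:
            raise ValueError(f"scope must be one of {_SCOPES}")


@dataclass
class HCModelConfig:
    interactive: bool = False           # focal x neighbor SDW interaction
    include_mrf: bool = True            # per-block MRF field
    optimizer: Optional[dict] = None


@dataclass
class SDWFit:
    fit: pmm.FitResult
    slopes: pd.DataFrame                # per-treatment neighbor slope, se, p
    slope_diffs: pd.DataFrame           # pairwise slope differences
    n_dropped: int
    pruned_terms: list


@dataclass
class HCFit:
    fit: pmm.FitResult
    terms: pd.DataFrame                 # focal / neighbor coefficient summary
    n_dropped: int


@dataclass
class CorrectionResult:
    data: pd.DataFrame                  # input rows + corrected phenotype
    corrected_col: str
    subtracted: pd.DataFrame            # centered per-term nuisance components
    kept_terms: list


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def lattice_adjacency(rows: int, cols: int) -> dict:
    """Queen adjacency over 'rXcY' cell labels of one block lattice."""
    layout = geometry.GridLayout(rows=rows, cols=cols)
    return {f"r{r}c{c}": {f"r{q[0]}c{q[1]}"
                          for q in geometry.first_order_neighbors(layout, (r, c))}
            for r, c in layout.positions()}


def _add_neighbor_sdw(plants: pd.DataFrame, rows: int, cols: int) -> pd.DataFrame:
    layout = geometry.GridLayout(rows=rows, cols=cols)
    plants = plants.copy()
    plants["neigh_sdw_g"] = np.nan
    for _, sub in plants.groupby(["run", "block"], sort=False):
        ok = sub["sdw_mg"].notna()
        value_map = {(r, c): s / 1000.0 for r, c, s in
                     zip(sub.loc[ok, "row"], sub.loc[ok, "col"], sub.loc[ok, "sdw_mg"])}
        nb = [geometry.neighbor_mean(layout, value_map, (r, c))
              for r, c in zip(sub["row"], sub["col"])]
        plants.loc[sub.index, "neigh_sdw_g"] = nb
    return plants


def _grid_dims(plants: pd.DataFrame) -> tuple:
    return int(plants["row"].max()), int(plants["col"].max())


def prepare_sdw_table(plants: pd.DataFrame) -> tuple:
    """Model table for the SDW analysis: drops rows without SDW or without
    any scored neighbor, adds the neighbor-mean covariate (g) and global
    box-axis coordinates.  Returns ``(table, n_dropped)``."""
    rows, cols = _grid_dims(plants)
    df = _add_neighbor_sdw(plants, rows, cols)
    n0 = len(df)
    df = df[df["sdw_mg"].notna() & np.isfinite(df["neigh_sdw_g"])].copy()
    df["gx"] = (df["block_order"] - 1) * rows + df["row"]
    df["gy"] = df["col"].astype(float)
    df["run"] = df["run"].astype(str)
    df["box"] = df["box"].astype(str)
    df["edge"] = df["edge"].astype(float)
    df["exterior"] = df["exterior"].astype(float)
    return df, n0 - len(df)


def prepare_hc_table(plants: pd.DataFrame) -> tuple:
    """Model table for the colonization analysis (AM-treatment plants with a
    scored colonization value); adds focal and neighbor SDW in grams."""
    rows, cols = _grid_dims(plants)
    df = _add_neighbor_sdw(plants, rows, cols)
    df = df[df["treatment"] == "RP+AM"]
    n0 = len(df)
    df = df[df["hyphae_pct"].notna() & df["sdw_mg"].notna()
            & np.isfinite(df["neigh_sdw_g"])].copy()
    if len(df) and not df["hyphae_pct"].between(0, 100).all():
        raise ValueError("colonization must lie in [0, 100]")
    df["sdw_g"] = df["sdw_mg"] / 1000.0
    df["run"] = df["run"].astype(str)
    return df, n0 - len(df)


# ---------------------------------------------------------------------------
# SDW model
# ---------------------------------------------------------------------------

_FORCED_FIXED = ["run", "treatment", "edge", "exterior", "neigh_sdw_g",
                 "treatment:neigh_sdw_g"]
_EXTRA_INTERACTIONS = ["run:treatment", "run:edge", "run:exterior",
                       "run:neigh_sdw_g", "treatment:edge", "treatment:exterior",
                       "edge:exterior", "edge:neigh_sdw_g", "exterior:neigh_sdw_g"]


def _sdw_spec(config: SDWModelConfig, extras: list, drop=()) -> pmm.ModelSpec:
    """Model spec for one scope; ``drop`` removes single-level factors."""
    fixed = list(_FORCED_FIXED)
    if not config.include_neighbor:
        fixed = [t for t in fixed if "neigh_sdw_g" not in t]
        extras = [t for t in extras if "neigh_sdw_g" not in t]
    for f in drop:
        fixed = [t for t in fixed if f not in t.split(":")]
        extras = [t for t in extras if f not in t.split(":")]
    random = [pmm.RandomTerm("subgroup"),
              pmm.RandomTerm("variety", nested_in="subgroup")]
    if config.include_gxt:
        random.append(pmm.RandomTerm("treatment:variety"))
    if config.scope == "common":
        sm = pmm.SmoothTerm("tensor2d", ("gx", "gy"), k=config.spline_k)
    elif config.scope == "per_box":
        sm = pmm.SmoothTerm("tensor2d", ("gx", "gy"), k=config.spline_k, by="box")
    else:
        sm = pmm.SmoothTerm("tensor2d", ("row", "col"), k=config.spline_k, by="block")
    return pmm.ModelSpec(
        response="sdw_mg", log_transform=True,
        fixed=fixed + extras,
        random=random, smooths=[sm],
        categorical={"run", "treatment", "box", "block"})


def _term_pvalue(fit: pmm.FitResult, term: str) -> float:
    """Wald chi-square p-value for all columns of one fixed term."""
    ix = [j for j, t in enumerate(fit.design.x_terms) if t == term]
    if not ix:
        return 1.0
    b = fit.beta_full[ix]
    V = fit.cov_fixed[np.ix_(ix, ix)]
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError:
        return 1.0
    return float(stats.chi2.sf(stat, len(ix)))


def _neighbor_slopes(fit: pmm.FitResult, treatments: list) -> tuple:
    """Per-treatment neighbor slope = base slope + treatment contrast."""
    names = fit.design.x_names
    p = len(names)
    base = names.index("neigh_sdw_g")
    rows, vecs = [], {}
    for t in treatments:
        v = np.zeros(p)
        v[base] = 1.0
        contrast = f"treatment[{t}]:neigh_sdw_g"
        if contrast in names:
            v[names.index(contrast)] = 1.0
        slope = float(v @ fit.beta_full[:p])
        se = float(np.sqrt(v @ fit.cov_fixed @ v))
        z = slope / se if se > 0 else np.nan
        rows.append({"treatment": t, "slope": slope, "se": se,
                     "p": 2 * stats.norm.sf(abs(z))})
        vecs[t] = v
    slopes = pd.DataFrame(rows)
    diffs = []
    for i in range(len(treatments)):
        for j in range(i + 1, len(treatments)):
            d = vecs[treatments[j]] - vecs[treatments[i]]
            est = float(d @ fit.beta_full[:p])
            se = float(np.sqrt(d @ fit.cov_fixed @ d))
            z = est / se if se > 0 else np.nan
            diffs.append({"pair": f"{treatments[j]} - {treatments[i]}",
                          "diff": est, "se": se, "p": 2 * stats.norm.sf(abs(z))})
    return slopes, pd.DataFrame(diffs)


def fit_sdw_model(plants: pd.DataFrame, config: Optional[SDWModelConfig] = None) -> SDWFit:
    """Fit the log-SDW spatial model.

    Rows without SDW (unplanted or dead) or without any scored neighbor are
    dropped and counted.  When ``config.all_interactions`` the remaining
    pairwise interactions among the positional fixed effects are added; with
    ``select_fixed`` they are pruned backward, one at a time, dropping the
    least significant term with p >= ``p_drop`` (smoothing parameters are
    held at the full-model estimates during the sweep, then re-estimated for
    the final model).  The treatment-specific neighbor slope is always kept.
    """
    config = config or SDWModelConfig()
    df, n_dropped = prepare_sdw_table(plants)
    if (df["sdw_mg"] <= 0).any():
        raise ValueError("SDW must be positive for the log transform")
    extras = list(_EXTRA_INTERACTIONS) if config.all_interactions else []
    single = [f for f in ("run", "treatment") if df[f].nunique() < 2]
    spec = _sdw_spec(config, extras, drop=single)
    design = pmm.build_design(spec, df)
    y = pmm.response_vector(spec, df)
    fit = pmm.fit_reml(design, y, optimizer=config.optimizer)

    pruned = []
    if config.select_fixed and extras:
        lams = dict(fit.lambdas)
        current = list(extras)
        while current:
            pvals = {t: _term_pvalue(fit, t) for t in current}
            worst = max(pvals, key=pvals.get)
            if pvals[worst] < config.p_drop:
                break
            current.remove(worst)
            pruned.append(worst)
            spec = _sdw_spec(config, current, drop=single)
            design = pmm.build_design(spec, df)
            fit = pmm.fit_reml(design, y, fixed_lambdas=lams)
        if pruned:  # final refit with free smoothing parameters
            fit = pmm.fit_reml(design, y, optimizer=config.optimizer)

    treatments = sorted(df["treatment"].unique())
    if config.include_neighbor:
        slopes, diffs = _neighbor_slopes(fit, treatments)
    else:
        slopes = pd.DataFrame(columns=["treatment", "slope", "se", "p"])
        diffs = pd.DataFrame(columns=["pair", "diff", "se", "p"])
    return SDWFit(fit=fit, slopes=slopes, slope_diffs=diffs,
                  n_dropped=n_dropped, pruned_terms=pruned)


def select_spatial_structure(plants: pd.DataFrame,
                             candidates=("common", "per_box", "per_block"),
                             config: Optional[SDWModelConfig] = None) -> tuple:
    """Fit one SDW model per spatial-trend scope and pick the BIC minimizer.

    Ties break toward the scope with fewer fields (candidate order common <
    per_box < per_block); non-convergent candidates are excluded and
    reported.  Returns ``(chosen_scope, table)`` where the table lists BIC
    and delta-BIC per candidate.
    """
    base = config or SDWModelConfig()
    rows, failed = [], []
    order = [s for s in _SCOPES if s in candidates]
    fits = {}
    for scope in order:
        cfg = SDWModelConfig(scope=scope, spline_k=base.spline_k,
                             include_neighbor=base.include_neighbor,
                             include_gxt=base.include_gxt,
                             all_interactions=base.all_interactions,
                             select_fixed=False, optimizer=base.optimizer)
        try:
            f = fit_sdw_model(plants, cfg)
            if not f.fit.converged:
                raise FloatingPointError("non-convergent")
            fits[scope] = f
            rows.append({"scope": scope, "bic": f.fit.bic, "aic": f.fit.aic,
                         "edf": sum(f.fit.edf.values())})
        except (FloatingPointError, np.linalg.LinAlgError) as e:
            failed.append((scope, str(e)))
    if len(rows) < 2:
        raise RuntimeError(f"fewer than 2 candidates converged (failed: {failed})")
    tab = pd.DataFrame(rows)
    best = tab["bic"].min()
    tab["delta_bic"] = tab["bic"] - best
    # first in candidate order within numerical tie -> fewest parameters
    chosen = tab.loc[tab["bic"] <= best + 1e-9, "scope"].iloc[0]
    tab.attrs["failed"] = failed
    tab.attrs["fits"] = fits
    return chosen, tab


# ---------------------------------------------------------------------------
# colonization model
# ---------------------------------------------------------------------------

def _hc_spec(config: HCModelConfig, adjacency: dict) -> pmm.ModelSpec:
    fixed = ["sdw_g", "neigh_sdw_g"]
    if config.interactive:
        fixed.append("sdw_g:neigh_sdw_g")
    smooths = []
    if config.include_mrf:
        smooths.append(pmm.SmoothTerm("mrf", ("cell",), adjacency=adjacency,
                                      by="block"))
    return pmm.ModelSpec(
        response="hyphae_pct", log_transform=False,
        fixed=fixed,
        random=[pmm.RandomTerm("subgroup"),
                pmm.RandomTerm("variety", nested_in="subgroup")],
        smooths=smooths,
        categorical={"block"})


def fit_hc_model(plants: pd.DataFrame, config: Optional[HCModelConfig] = None) -> HCFit:
    """Fit the colonization model with its per-block MRF field."""
    config = config or HCModelConfig()
    df, n_dropped = prepare_hc_table(plants)
    rows, cols = _grid_dims(plants)
    adjacency = lattice_adjacency(rows, cols)
    spec = _hc_spec(config, adjacency)
    design = pmm.build_design(spec, df)
    y = pmm.response_vector(spec, df)
    fit = pmm.fit_reml(design, y, optimizer=config.optimizer)
    coef = fit.coefficients
    keep = coef["term"].isin(["sdw_g", "neigh_sdw_g", "sdw_g:neigh_sdw_g"])
    return HCFit(fit=fit, terms=coef[keep].reset_index(drop=True), n_dropped=n_dropped)


def compare_additive_interactive(plants: pd.DataFrame,
                                 optimizer: Optional[dict] = None) -> tuple:
    """AIC difference (interactive - additive) between the two HC variants."""
    add = fit_hc_model(plants, HCModelConfig(interactive=False, optimizer=optimizer))
    inter = fit_hc_model(plants, HCModelConfig(interactive=True, optimizer=optimizer))
    return inter.fit.aic - add.fit.aic, add, inter


# ---------------------------------------------------------------------------
# spatial correction
# ---------------------------------------------------------------------------

_DEFAULT_KEEP = ("(Intercept)", "treatment", "subgroup", "variety%in%subgroup",
                 "treatment:variety")


def spatially_correct(fit: pmm.FitResult, data: pd.DataFrame,
                      keep=_DEFAULT_KEEP, subtract=None,
                      corrected_col: Optional[str] = None) -> CorrectionResult:
    """Remove fitted position/neighbor components from the phenotype.

    Every component term not in ``keep`` (or, if ``subtract`` is given,
    exactly those terms) is centered to mean zero over the observations and
    subtracted from the transformed response; the residual stays.  For a
    log-transformed response the subtraction happens on the log scale and
    the corrected value is exponentiated back.  ``data`` must be the table
    the model was fitted to (same row order).
    """
    comp = fit.components
    if len(data) != len(comp):
        raise ValueError("data does not match the fitted observations")
    terms = [c for c in comp.columns if c != "residual"]
    if subtract is not None:
        missing = [t for t in subtract if t not in terms]
        if missing:
            raise KeyError(f"terms not in the fit: {missing}")
        nuisance = list(subtract)
    else:
        nuisance = [t for t in terms if t not in keep]
    kept = [t for t in terms if t not in nuisance]

    spec = fit.design.spec
    y = fit.y.copy()
    centered = comp[nuisance] - comp[nuisance].mean()
    corrected = y - centered.to_numpy().sum(axis=1) if nuisance else y.copy()

    out = data.copy()
    name = corrected_col or f"{spec.response}_corrected"
    out[name] = np.exp(corrected) if spec.log_transform else corrected
    return CorrectionResult(data=out, corrected_col=name,
                            subtracted=centered, kept_terms=kept)
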