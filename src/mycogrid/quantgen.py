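"""Variance partitioning, broad-sense heritability and cultivar summaries.

One-way partitions report the fraction of the total sum of squares explained
by a grouping factor together with a plot-level broad-sense heritability from
the ANOVA expected mean squares,

    H2 = s2_G / (s2_G + s2_E),   s2_G = (MS_G - MS_E) / r_bar,

with the unbalanced replicate coefficient ``r_bar = (N - sum n_i^2 / N) / (k - 1)``
and negative variance estimates truncated at zero.  Two-way partitions use
Type II sums of squares (appropriate for unbalanced main-effect shares),
computed via :mod:`statsmodels`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["VariancePartition", "oneway_partition", "twoway_partition", "cultivar_summaries"]


@dataclass
class VariancePartition:
    shares: dict                 # factor -> percent of total SS (incl. "residual")
    p_values: dict
    h2: Optional[float] = None
    r_bar: Optional[float] = None
    variance_shares: Optional[dict] = None   # EMS variance components, percent
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        tot = sum(self.shares.values())
        if abs(tot - 100.0) > 1e-6:
            raise ValueError(f"shares must sum to 100, got {tot}")


def oneway_partition(values, groups) -> VariancePartition:
    """One-way ANOVA share and broad-sense heritability for one factor."""
    y = np.asarray(values, float)
    g = np.asarray(groups)
    ok = np.isfinite(y)
    y, g = y[ok], g[ok]
    levels, inv = np.unique(g, return_inverse=True)
    k, N = len(levels), len(y)
    if k < 2:
        raise ValueError("one-way partition needs at least 2 groups")
    if N <= k:
        raise ValueError("need replication within groups")
    counts = np.bincount(inv)
    means = np.bincount(inv, weights=y) / counts
    gm = y.mean()
    ss_g = float(np.sum(counts * (means - gm) ** 2))
    ss_t = float(np.sum((y - gm) ** 2))
    ss_e = ss_t - ss_g
    ms_g = ss_g / (k - 1)
    ms_e = ss_e / (N - k)
    r_bar = (N - np.sum(counts**2) / N) / (k - 1)
    s2_g = max((ms_g - ms_e) / r_bar, 0.0)
    h2 = s2_g / (s2_g + ms_e) if (s2_g + ms_e) > 0 else 0.0
    from scipy import stats
    p = float(stats.f.sf(ms_g / ms_e, k - 1, N - k)) if ms_e > 0 else 0.0
    if ss_t == 0:
        share_g, share_e = 0.0, 100.0
    else:
        share_g = 100.0 * ss_g / ss_t
        share_e = 100.0 * ss_e / ss_t
    return VariancePartition(shares={"group": share_g, "residual": share_e},
                             p_values={"group": p}, h2=float(h2), r_bar=float(r_bar))


def twoway_partition(values, cultivar, treatment) -> VariancePartition:
    """Two-way ANOVA (main effects + interaction) with Type II sums of squares.

    Shares are each term's SS as a percent of the sum of all term SS plus the
    residual SS, so they total 100 even in unbalanced data.
    """
    df = pd.DataFrame({"y": np.asarray(values, float),
                       "cultivar": np.asarray(cultivar).astype(str),
                       "treatment": np.asarray(treatment).astype(str)})
    df = df[np.isfinite(df["y"])]
    warnings = []
    for f in ("cultivar", "treatment"):
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    cells = df.groupby(["cultivar", "treatment"]).size()
    full_cells = df["cultivar"].nunique() * df["treatment"].nunique()
    if len(cells) < full_cells:
        warnings.append(f"{full_cells - len(cells)} empty cells; "
                        "interaction computed on available cells")
    model = smf.ols("y ~ C(cultivar) + C(treatment) + C(cultivar):C(treatment)",
                    data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    ss = tab["sum_sq"]
    labels = {"C(cultivar)": "cultivar", "C(treatment)": "treatment",
              "C(cultivar):C(treatment)": "cultivar:treatment", "Residual": "residual"}
    total = float(ss.sum())
    shares = {labels[i]: 100.0 * float(v) / total for i, v in ss.items()}
    pvals = {labels[i]: float(tab.loc[i, "PR(>F)"]) for i in tab.index if i != "Residual"}

    # EMS variance components (both factors random, crossed):
    #   E[MS_C]  = s2e + r s2ct + r nT s2c ; E[MS_T] analogous
    #   E[MS_CT] = s2e + r s2ct           ; E[MS_E] = s2e
    ms = tab["sum_sq"] / tab["df"]
    n_c = df["cultivar"].nunique()
    n_t = df["treatment"].nunique()
    r = len(df) / (n_c * n_t)
    s2e = float(ms["Residual"])
    s2ct = max((float(ms["C(cultivar):C(treatment)"]) - s2e) / r, 0.0)
    s2c = max((float(ms["C(cultivar)"]) - s2e - r * s2ct) / (r * n_t), 0.0)
    s2t = max((float(ms["C(treatment)"]) - s2e - r * s2ct) / (r * n_c), 0.0)
    tot_var = s2c + s2t + s2ct + s2e
    variance_shares = {
        "cultivar": 100.0 * s2c / tot_var, "treatment": 100.0 * s2t / tot_var,
        "cultivar:treatment": 100.0 * s2ct / tot_var, "residual": 100.0 * s2e / tot_var,
    } if tot_var > 0 else None
    return VariancePartition(shares=shares, p_values=pvals,
                             variance_shares=variance_shares, warnings=warnings)


def cultivar_summaries(values, groups) -> pd.DataFrame:
    """Per-cultivar mean, SD, CV plus the distribution-wide extremes.

    Returns a frame indexed by cultivar with columns ``mean``, ``sd``, ``cv``,
    ``n`` and attrs ``avg_cv`` (mean CV over cultivars with defined CV),
    ``min_cultivar`` / ``max_cultivar``.  Single-observation cultivars have
    no SD and are excluded from the average CV, as are cultivars with mean 0.
    """
    df = pd.DataFrame({"y": np.asarray(values, float), "g": np.asarray(groups)})
    df = df[np.isfinite(df["y"])]
    agg = df.groupby("g")["y"].agg(mean="mean", sd="std", n="size")
    cv = agg["sd"] / agg["mean"].where(agg["mean"] != 0)
    agg["cv"] = cv
    agg.index.name = "cultivar"
    valid = agg["cv"].dropna()
    agg.attrs["avg_cv"] = float(valid.mean()) if len(valid) else float("nan")
    agg.attrs["min_cultivar"] = agg["mean"].idxmin()
    agg.attrs["max_cultivar"] = agg["mean"].idxmax()
    return agg
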