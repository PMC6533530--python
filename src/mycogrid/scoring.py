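"""Magnified-intersections colonization scoring.

Each examined root--graticule intersection is recorded as exactly one of
``none``, ``hyphae_only``, ``arbuscule`` or ``vesicle`` (arbuscules and
vesicles take precedence over plain hyphae since either implies hyphae are
present).  Per-plant percentages are category counts over the total number
of intersections; total hyphal colonization is the sum of the three positive
categories, which cannot double-count because the categories are exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

CATEGORIES = ("none", "hyphae_only", "arbuscule", "vesicle")

__all__ = ["IntersectionRecord", "PlantScore", "score_plant", "score_table", "CATEGORIES"]


@dataclass(frozen=True)
class IntersectionRecord:
    plant_id: str
    category: str

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown intersection category {self.category!r}")


@dataclass(frozen=True)
class PlantScore:
    hyphae_only_pct: float
    arbuscule_pct: float
    vesicle_pct: float
    hyphal_total_pct: float


def score_plant(records) -> PlantScore:
    """Percent colonization from one plant's intersection records."""
    cats = [r.category if isinstance(r, IntersectionRecord) else str(r) for r in records]
    for c in cats:
        if c not in CATEGORIES:
            raise ValueError(f"unknown intersection category {c!r}")
    n = len(cats)
    if n == 0:
        raise ValueError("cannot score a plant with zero intersections")
    h = 100.0 * cats.count("hyphae_only") / n
    a = 100.0 * cats.count("arbuscule") / n
    v = 100.0 * cats.count("vesicle") / n
    return PlantScore(h, a, v, h + a + v)


def score_table(df: pd.DataFrame) -> pd.DataFrame:
    """Score a long table (plant, category) into per-plant percentages.

    Expects columns ``plant`` and ``category``; returns one row per plant
    with the four percentage columns.
    """
    for c in ("plant", "category"):
        if c not in df.columns:
            raise ValueError(f"intersection table missing column {c!r}")
    rows = []
    for plant, sub in df.groupby("plant", sort=True):
        s = score_plant(sub["category"].tolist())
        rows.append({"plant": plant, "hyphae_only_pct": s.hyphae_only_pct,
                     "arbuscule_pct": s.arbuscule_pct, "vesicle_pct": s.vesicle_pct,
                     "hyphal_total_pct": s.hyphal_total_pct})
    return pd.DataFrame(rows)
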