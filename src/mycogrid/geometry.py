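"""Physical layout of the box screen.

Each run uses one plywood box divided into three treatment blocks arranged
along the long (north--south) axis of the box.  Within a block, plants sit on
a regular ``rows x cols`` lattice (17 x 20 by default, 5 cm spacing).
Neighborhood is queen-style: the up-to-8 horizontally, vertically and
diagonally adjacent cells, never crossing the dividers between treatment
blocks.

Coordinates are 1-based ``(row, col)`` within a block; ``row`` runs along the
box axis, so a block's first and last rows face either a box wall (blocks 1
and 3 at the box ends) or an internal divider.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "GridLayout",
    "AdjacencyGraph",
    "first_order_neighbors",
    "edge_flags",
    "neighbor_mean",
    "build_adjacency",
    "read_layout_csv",
    "write_layout_csv",
]


@dataclass(frozen=True)
class GridLayout:
    """One treatment block's planting lattice.

    Parameters
    ----------
    rows, cols
        Lattice dimensions (default 17 x 20 = 340 positions).
    spacing_cm
        Plant-to-plant spacing; informational only, the analysis works on
        the lattice.
    block_id
        Identifier of the run x treatment block this lattice belongs to.
    block_order_in_box
        1..3 position of the block along the box axis; determines which of
        its short faces are external box walls.
    """

    rows: int = 17
    cols: int = 20
    spacing_cm: float = 5.0
    block_id: str = "block"
    block_order_in_box: int = 1

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have positive dimensions")
        if self.spacing_cm <= 0:
            raise ValueError("spacing must be positive")
        if self.block_order_in_box not in (1, 2, 3):
            raise ValueError("block_order_in_box must be 1, 2 or 3")

    @property
    def n_positions(self) -> int:
        return self.rows * self.cols

    def positions(self):
        """Iterate all 1-based (row, col) positions, row-major."""
        return itertools.product(range(1, self.rows + 1), range(1, self.cols + 1))

    def contains(self, position) -> bool:
        r, c = position
        return 1 <= r <= self.rows and 1 <= c <= self.cols


def first_order_neighbors(layout: GridLayout, position) -> set:
    """The <=8 queen-adjacent positions of ``position`` within the block.

    Neighborhoods never cross the divider into an adjacent treatment block,
    so corner plants have 3 neighbors, non-corner edge plants 5, interior
    plants 8.
    """
    if not layout.contains(position):
        raise ValueError(f"position {position} outside {layout.rows}x{layout.cols} grid")
    r, c = position
    out = set()
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            p = (r + dr, c + dc)
            if layout.contains(p):
                out.add(p)
    return out


def edge_flags(layout: GridLayout, position) -> tuple:
    """``(edge, exterior)`` 0/1 flags for a position.

    ``edge`` is 1 on the outermost ring of the block.  ``exterior`` is 1 only
    where that ring coincides with a physical box wall: the long sides of the
    box (first/last column) for every block, plus the short box ends --
    the first row of block 1 and the last row of block 3.  The two faces of
    the middle block along the box axis abut internal dividers and are not
    exterior; the same holds for the divider-facing rows of blocks 1 and 3.
    """
    if not layout.contains(position):
        raise ValueError(f"position {position} outside grid")
    r, c = position
    on_long_side = c == 1 or c == layout.cols
    on_first_row = r == 1
    on_last_row = r == layout.rows
    edge = on_long_side or on_first_row or on_last_row
    if not edge:
        return (0, 0)
    exterior = on_long_side
    if layout.block_order_in_box == 1 and on_first_row:
        exterior = True
    if layout.block_order_in_box == 3 and on_last_row:
        exterior = True
    return (1, int(exterior))


def neighbor_mean(layout: GridLayout, value_map: dict, position) -> float:
    """Arithmetic mean of a value over the available first-order neighbors.

    Positions absent from ``value_map`` (missing/dead plants) are skipped.
    Returns NaN when no neighbor has a value.
    """
    vals = [value_map[p] for p in first_order_neighbors(layout, position) if p in value_map]
    if not vals:
        return float("nan")
    return sum(vals) / len(vals)


@dataclass
class AdjacencyGraph:
    """Queen adjacency of one block as an undirected graph."""

    layout: GridLayout
    graph: nx.Graph = field(repr=False)

    def degree_histogram(self) -> dict:
        hist: dict = {}
        for _, d in self.graph.degree():
            hist[d] = hist.get(d, 0) + 1
        return hist


def build_adjacency(layout: GridLayout) -> AdjacencyGraph:
    g = nx.Graph()
    g.add_nodes_from(layout.positions())
    for p in layout.positions():
        for q in first_order_neighbors(layout, p):
            g.add_edge(p, q)
    return AdjacencyGraph(layout=layout, graph=g)


_LAYOUT_COLUMNS = ["run", "box", "block", "treatment", "row", "col", "variety", "subgroup"]


def read_layout_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"layout file missing columns: {missing}")
    return df


def write_layout_csv(df: pd.DataFrame, path) -> None:
    missing = [c for c in _LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"layout frame missing columns: {missing}")
    df.to_csv(path, index=False)
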