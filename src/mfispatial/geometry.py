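"""Signed distances to anatomical landmarks, binning, adjacency and matching.

Conventions (units are 0.5-um pixels throughout):

* ``d_interface``: unsigned part is the Euclidean distance to the interface
  polyline; the sign is + on the maternal side and - on the fetal side.
* ``d_vessel``: distance to the nearest vessel wall; + intraluminal (inside
  the polygon), - extraluminal, 0 on the wall.
* Distance bins are half-open ``[k*W, (k+1)*W)``.

The interface polyline must be single-valued in x (vertices with strictly
increasing x); the maternal side is "above" or "below" that graph. For cells
beyond the polyline's x-extent the distance falls back to the nearest
endpoint and the side test uses the endpoint's y.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, Polygon

from ._stats import rank_sum_p

MATERNAL = "maternal"
FETAL = "fetal"


# ---------------------------------------------------------------------------
# interface distance


def _clean_polyline(coords: np.ndarray) -> np.ndarray:
    """Drop zero-length segments; error on degenerate polylines."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 2:
        raise ValueError("interface polyline needs at least 2 vertices")
    keep = np.ones(len(coords), dtype=bool)
    keep[1:] = np.any(np.diff(coords, axis=0) != 0.0, axis=1)
    coords = coords[keep]
    if coords.shape[0] < 2:
        raise ValueError("interface polyline is fully degenerate (single point)")
    return coords


def interface_y_at(interface: LineString, x: np.ndarray) -> np.ndarray:
    """Piecewise-linear interface height y(x), endpoint-extended beyond its span."""
    coords = _clean_polyline(np.asarray(interface.coords))
    vx, vy = coords[:, 0], coords[:, 1]
    if np.any(np.diff(vx) <= 0):
        order = np.argsort(vx, kind="stable")
        vx, vy = vx[order], vy[order]
    return np.interp(np.asarray(x, dtype=float), vx, vy)


def signed_distance_to_interface(
    cells: pd.DataFrame,
    interface: LineString,
    maternal_side: str = "above",
) -> pd.DataFrame:
    """Per-cell signed distance to the interface polyline.

    Returns a DataFrame indexed like ``cells`` with columns
    ``d_interface_px`` (signed, + maternal) and ``compartment``.
    """
    if maternal_side not in ("above", "below"):
        raise ValueError(f"maternal_side must be 'above' or 'below', got {maternal_side!r}")
    coords = _clean_polyline(np.asarray(interface.coords))
    line = LineString(coords)
    pts = shapely.points(cells["x_px"].to_numpy(float), cells["y_px"].to_numpy(float))
    dist = shapely.distance(pts, line)
    y_line = interface_y_at(line, cells["x_px"].to_numpy(float))
    above = cells["y_px"].to_numpy(float) >= y_line
    maternal = above if maternal_side == "above" else ~above
    signed = np.where(maternal, dist, -dist)
    signed = np.where(dist == 0.0, 0.0, signed)
    comp = np.where(maternal | (dist == 0.0), MATERNAL, FETAL)
    return pd.DataFrame(
        {"d_interface_px": signed, "compartment": comp}, index=cells.index
    )


# ---------------------------------------------------------------------------
# vessel distance


def signed_distance_to_vessel(
    cells: pd.DataFrame,
    vessels: Mapping[int, Polygon],
) -> pd.DataFrame:
    """Per-cell signed distance to the nearest vessel wall.

    + inside the vessel polygon (intraluminal), - outside, 0 on the wall.
    ``nearest_vessel_id`` ties are broken toward the lowest vessel id.
    """
    if not vessels:
        raise ValueError("at least one vessel polygon is required")
    x = cells["x_px"].to_numpy(float)
    y = cells["y_px"].to_numpy(float)
    pts = shapely.points(x, y)
    best = np.full(len(cells), np.inf)
    best_id = np.full(len(cells), -1, dtype=int)
    best_signed = np.zeros(len(cells))
    for vid in sorted(vessels):
        poly = vessels[vid]
        d = shapely.distance(pts, poly.exterior)
        inside = shapely.contains_xy(poly, x, y)
        signed = np.where(inside, d, -d)
        signed = np.where(d == 0.0, 0.0, signed)
        better = d < best  # strict: first (lowest) id wins ties
        best = np.where(better, d, best)
        best_signed = np.where(better, signed, best_signed)
        best_id = np.where(better, vid, best_id)
    return pd.DataFrame(
        {"d_vessel_px": best_signed, "nearest_vessel_id": best_id}, index=cells.index
    )


def compute_distances(section) -> pd.DataFrame:
    """Full distance table for a :class:`~mfispatial.io.TissueSection`.

    Columns: d_interface_px, compartment, and -- when the section has
    vessels -- d_vessel_px, nearest_vessel_id and ``vessel_eligible`` (False
    for fetal-compartment cells, which the vessel-proximity analyses exclude).
    """
    out = signed_distance_to_interface(
        section.cells, section.interface, section.maternal_side
    )
    if section.vessels:
        dv = signed_distance_to_vessel(section.cells, section.vessels)
        out = out.join(dv)
        out["vessel_eligible"] = out["compartment"] == MATERNAL
    return out


# ---------------------------------------------------------------------------
# composition binning


@dataclass
class BinningConfig:
    """Distance-bin layout: half-open bins of ``bin_width`` px."""

    bin_width: float = 100.0
    max_range: float | None = None
    side: str = "both"  # maternal | fetal | both

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.side not in ("maternal", "fetal", "both"):
            raise ValueError(f"unknown side restriction {self.side!r}")


@dataclass
class CompositionProfile:
    """Per-bin cell-type counts and proportions.

    ``counts`` and ``proportions`` are bin x cell-type DataFrames indexed by
    the lower bin edge; ``n`` is the per-bin total.
    """

    counts: pd.DataFrame
    proportions: pd.DataFrame
    n: pd.Series
    bin_width: float


def bin_composition(
    distances: pd.Series,
    labels: pd.Series,
    config: BinningConfig | None = None,
) -> CompositionProfile:
    """Cell-type composition in concentric distance bins.

    ``distances`` may be signed (interface) or absolute (vessel); bins are
    ``[k*W, (k+1)*W)`` for integer k (negative bins cover the fetal /
    extraluminal side when signed distances are passed).
    """
    config = config or BinningConfig()
    d = distances.astype(float)
    labels = labels.reindex(d.index)
    mask = d.notna() & labels.notna()
    if config.side == "maternal":
        mask &= d >= 0
    elif config.side == "fetal":
        mask &= d < 0
    if config.max_range is not None:
        mask &= d.abs() <= config.max_range
    d, labels = d[mask], labels[mask]
    if len(d) == 0:
        empty = pd.DataFrame(dtype=float)
        return CompositionProfile(empty, empty, pd.Series(dtype=float), config.bin_width)
    k = np.floor(d.to_numpy() / config.bin_width).astype(int)
    edges = pd.Series(k * config.bin_width, index=d.index, name="bin_lo")
    counts = (
        pd.crosstab(edges, labels).sort_index()
    )
    n = counts.sum(axis=1)
    proportions = counts.div(n, axis=0)
    return CompositionProfile(counts, proportions, n, config.bin_width)


# ---------------------------------------------------------------------------
# tile adjacency


def tile_adjacency(
    cells: pd.DataFrame,
    tile_px: float = 50.0,
    k_tiles: int = 5,
    between: tuple[Iterable, Iterable] | None = None,
) -> pd.DataFrame:
    """Grid-tile neighbour pairs.

    Cells are binned onto a square grid of side ``tile_px``; two cells are
    adjacent iff the Chebyshev distance between their tiles is <= ``k_tiles``.
    With ``between=(ids_a, ids_b)`` only cross pairs (a, b) are returned;
    otherwise all unordered pairs (cell_a < cell_b), self-pairs excluded.
    """
    if tile_px <= 0:
        raise ValueError("tile_px must be > 0")
    if k_tiles < 0:
        raise ValueError("k_tiles must be >= 0")
    tx = np.floor(cells["x_px"].to_numpy(float) / tile_px).astype(int)
    ty = np.floor(cells["y_px"].to_numpy(float) / tile_px).astype(int)
    tiles = pd.DataFrame({"tx": tx, "ty": ty}, index=cells.index)
    if between is not None:
        ids_a, ids_b = pd.Index(between[0]), pd.Index(between[1])
    else:
        ids_a = ids_b = cells.index
    ta = tiles.loc[ids_a]
    tb = tiles.loc[ids_b]
    bucket: dict[tuple[int, int], list] = {}
    for cid, bx, by in zip(tb.index, tb["tx"], tb["ty"]):
        bucket.setdefault((bx, by), []).append(cid)
    pairs_a, pairs_b = [], []
    offsets = [
        (dx, dy)
        for dx in range(-k_tiles, k_tiles + 1)
        for dy in range(-k_tiles, k_tiles + 1)
    ]
    for cid, bx, by in zip(ta.index, ta["tx"], ta["ty"]):
        for dx, dy in offsets:
            for other in bucket.get((bx + dx, by + dy), ()):
                if between is None:
                    if not (cid < other):
                        continue
                elif cid == other:
                    continue
                pairs_a.append(cid)
                pairs_b.append(other)
    return pd.DataFrame({"cell_a": pairs_a, "cell_b": pairs_b})


# ---------------------------------------------------------------------------
# depth matching


@dataclass
class MatchResult:
    """Depth-matched control set with a post-hoc balance check."""

    matched_ids: pd.Index
    pvalue: float
    dropped_bins: list = field(default_factory=list)


def depth_match(
    group_depths: pd.Series,
    pool_depths: pd.Series,
    bin_px: float = 100.0,
    seed: int | np.random.Generator = 0,
) -> MatchResult:
    """Stratified sampling of a depth-matched control set.

    Pool cells are drawn without replacement so that the matched set's depth
    histogram (half-open bins of ``bin_px``) equals the target group's, capped
    at each stratum's pool count. The reported p-value is a two-sided rank-sum
    test on depths (target vs matched); large values indicate balance.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if bin_px <= 0:
        raise ValueError("bin_px must be > 0")
    gbins = np.floor(group_depths.to_numpy(float) / bin_px).astype(int)
    pbins = pd.Series(
        np.floor(pool_depths.to_numpy(float) / bin_px).astype(int),
        index=pool_depths.index,
    )
    chosen: list = []
    dropped: list = []
    want = pd.Series(gbins).value_counts().sort_index()
    for b, n_want in want.items():
        candidates = pbins.index[pbins == b]
        if len(candidates) == 0:
            dropped.append(int(b))
            warnings.warn(
                f"depth_match: no pool cells in bin [{b * bin_px}, {(b + 1) * bin_px}); stratum dropped"
            )
            continue
        take = min(int(n_want), len(candidates))
        pick = rng.choice(len(candidates), size=take, replace=False)
        chosen.extend(candidates[np.sort(pick)])
    if not chosen:
        raise ValueError("depth_match: every stratum of the pool is empty")
    matched = pd.Index(chosen)
    p = rank_sum_p(group_depths.to_numpy(float), pool_depths.loc[matched].to_numpy(float))
    return MatchResult(matched, p, dropped)
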