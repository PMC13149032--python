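"""EVT density adjacent to vessel walls versus randomized decidual regions.

For each vessel, the EVT density of its outer annulus (wall to ``w`` px
outward) is compared against densities in congruent annuli dropped uniformly
at random into the decidua (the maternal compartment), rejecting placements
that cross the interface or intersect any vessel lumen. A two-sided Wilcoxon
rank-sum test compares the vessel densities with the pooled null densities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely import affinity
from shapely.geometry import LineString, Polygon, box
from shapely.ops import unary_union

from . import geometry
from ._stats import rank_sum_p

_QUAD_SEGS = 64  # buffer resolution; keeps annulus areas within ~1e-4 of analytic


@dataclass
class RegionSpec:
    """Annulus geometry and null-sampling parameters."""

    annulus_width_px: float = 100.0
    draws_per_vessel: int = 10
    max_attempts: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.annulus_width_px <= 0:
            raise ValueError("annulus_width_px must be > 0")
        if self.draws_per_vessel < 1:
            raise ValueError("draws_per_vessel must be >= 1")


@dataclass
class EnrichmentResult:
    vessel_densities: pd.Series
    null_densities: np.ndarray
    statistic: float
    pvalue: float
    n_vessels: int
    n_null: int


def section_bounds(section) -> Polygon:
    xs = [c[0] for c in section.interface.coords]
    x0, x1 = min(xs), max(xs)
    ys = section.cells["y_px"]
    y_top = max(
        float(ys.max()) if len(ys) else 0.0,
        max(c[1] for c in section.interface.coords),
    )
    for poly in section.vessels.values():
        y_top = max(y_top, poly.bounds[3])
    return box(x0, 0.0, x1, y_top)


def maternal_polygon(section) -> Polygon:
    """Polygon of the maternal compartment (decidua side of the interface)."""
    bounds = section_bounds(section)
    x0, y0, x1, y1 = bounds.bounds
    coords = list(section.interface.coords)
    if section.maternal_side == "above":
        ring = coords + [(x1, y1 + 1), (x0, y1 + 1)]
    else:
        ring = coords + [(x1, y0 - 1), (x0, y0 - 1)]
    poly = Polygon(ring)
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly.intersection(bounds)


def _annulus(poly: Polygon, w: float):
    return poly.buffer(w, quad_segs=_QUAD_SEGS).difference(poly)


def evt_density_near_vessels(
    section,
    distances: pd.DataFrame,
    spec: RegionSpec | None = None,
    evt_label: str = "EVT",
) -> pd.DataFrame:
    """Per-vessel EVT density in the outer wall annulus.

    Density = (EVTs with ``-w <= d_vessel <= 0`` attributed to the vessel) /
    (area of the polygon buffered outward by ``w`` minus the polygon area).
    Fetal-compartment cells are excluded.
    """
    spec = spec or RegionSpec()
    w = spec.annulus_width_px
    cells = section.cells
    is_evt = cells["cell_type"] == evt_label
    eligible = distances.get("vessel_eligible")
    if eligible is not None:
        is_evt &= eligible.reindex(cells.index).fillna(False)
    dv = distances["d_vessel_px"].reindex(cells.index)
    vid = distances["nearest_vessel_id"].reindex(cells.index)
    in_annulus = is_evt & (dv >= -w) & (dv <= 0)
    rows = []
    for v in sorted(section.vessels):
        area = _annulus(section.vessels[v], w).area
        if area <= 0:
            raise ValueError(f"vessel {v}: annulus has zero area")
        n = int((in_annulus & (vid == v)).sum())
        rows.append({"vessel_id": v, "n_evt": n, "area_px2": area, "density": n / area})
    return pd.DataFrame(rows).set_index("vessel_id")


def sample_null_regions(
    section,
    spec: RegionSpec | None = None,
    evt_label: str = "EVT",
) -> pd.DataFrame:
    """EVT densities of randomly placed congruent annuli in the decidua.

    For each vessel, ``draws_per_vessel`` copies of its annulus are dropped
    uniformly at random (by translation) into the maternal compartment;
    placements whose annulus leaves the section, crosses into the fetal
    compartment, or intersects any vessel lumen are rejected and redrawn.
    """
    spec = spec or RegionSpec()
    rng = np.random.default_rng(spec.seed)
    w = spec.annulus_width_px
    bounds = section_bounds(section)
    x0, y0, x1, y1 = bounds.bounds
    maternal = maternal_polygon(section)
    fetal = bounds.difference(maternal)
    lumens = unary_union(list(section.vessels.values())) if section.vessels else None
    cells = section.cells
    evt = cells[cells["cell_type"] == evt_label]
    ex = evt["x_px"].to_numpy(float)
    ey = evt["y_px"].to_numpy(float)

    rows = []
    for v in sorted(section.vessels):
        poly = section.vessels[v]
        ring = _annulus(poly, w)
        area = ring.area
        cx0, cy0, cx1, cy1 = ring.bounds
        half_w, half_h = (cx1 - cx0) / 2, (cy1 - cy0) / 2
        ccx, ccy = (cx0 + cx1) / 2, (cy0 + cy1) / 2
        for draw in range(spec.draws_per_vessel):
            for _attempt in range(spec.max_attempts):
                tx = rng.uniform(x0 + half_w, x1 - half_w) - ccx
                ty = rng.uniform(y0 + half_h, y1 - half_h) - ccy
                cand = affinity.translate(ring, tx, ty)
                if cand.intersects(fetal):
                    continue
                if lumens is not None and cand.intersects(lumens):
                    continue
                break
            else:
                raise ValueError(
                    f"vessel {v}: could not place null annulus after {spec.max_attempts} attempts"
                )
            bx0, by0, bx1, by1 = cand.bounds
            near = (ex >= bx0) & (ex <= bx1) & (ey >= by0) & (ey <= by1)
            n = int(shapely.contains_xy(cand, ex[near], ey[near]).sum()) if near.any() else 0
            rows.append({"vessel_id": v, "draw": draw, "density": n / area})
    return pd.DataFrame(rows)


def enrichment_test(
    vessel_densities: pd.Series | np.ndarray,
    null_densities: pd.Series | np.ndarray,
) -> EnrichmentResult:
    """Two-sided rank-sum comparison of vessel vs null annulus densities.

    Exact enumeration when both samples have <= 10 untied values, otherwise
    the tie-corrected normal approximation.
    """
    v = np.asarray(pd.Series(vessel_densities), dtype=float)
    nl = np.asarray(pd.Series(null_densities), dtype=float)
    if v.size == 0 or nl.size == 0:
        raise ValueError("both density groups must be nonempty")
    p = rank_sum_p(v, nl)
    from scipy.stats import mannwhitneyu

    stat = float(mannwhitneyu(v, nl, alternative="two-sided").statistic)
    return EnrichmentResult(
        vessel_densities=pd.Series(v),
        null_densities=nl,
        statistic=stat,
        pvalue=p,
        n_vessels=int(v.size),
        n_null=int(nl.size),
    )


def run_enrichment(
    section,
    distances: pd.DataFrame,
    spec: RegionSpec | None = None,
    evt_label: str = "EVT",
) -> EnrichmentResult:
    """Convenience: densities, null sampling and the pooled test in one call."""
    spec = spec or RegionSpec()
    obs = evt_density_near_vessels(section, distances, spec, evt_label)
    null = sample_null_regions(section, spec, evt_label)
    return enrichment_test(obs["density"], null["density"])
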