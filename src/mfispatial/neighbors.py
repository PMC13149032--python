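"""Local effect of stromal-subtype adjacency on EVT invasiveness.

EVTs are grouped by their grid-tile neighbourhood relative to decidual
stromal cells (DSCs): adjacent to the focal subtype (e.g. DSC4), adjacent to
other DSC subtypes only, or not adjacent to any DSC. The last group is
depth-matched to the focal group before comparison so that the superficial
localization of the focal subtype cannot masquerade as a score difference.
Contrasts are two-sided rank-sum tests with BH correction over the two
headline comparisons, with the focal-vs-matched depth balance reported as a
check (expected non-significant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geometry
from ._stats import bh_adjust, rank_sum_p


@dataclass
class AdjacencyGroups:
    focal_subtype: str
    adjacent_focal: pd.Index
    adjacent_other: pd.Index
    matched_control: pd.Index
    focal_matched: pd.Index  # focal cells trimmed to the control's depth histogram
    nonadjacent_pool: pd.Index
    depth_match_pvalue: float


@dataclass
class AdjacencyContrast:
    focal_subtype: str
    group_medians: dict
    group_n: dict
    pvalues: pd.Series  # raw, per contrast
    p_adjusted: pd.Series
    depth_balance_pvalue: float


def assign_adjacency_groups(
    evt_cells: pd.DataFrame,
    dsc_cells: pd.DataFrame,
    pairs: pd.DataFrame,
    depths: pd.Series,
    focal_subtype: str = "DSC4",
    bin_px: float = 100.0,
    seed: int | np.random.Generator = 0,
    priority: str = "focal",
) -> AdjacencyGroups:
    """Partition EVTs by DSC adjacency and build a depth-matched control set.

    ``pairs`` holds tile-neighbour pairs (cell_a = EVT, cell_b = DSC) from
    :func:`mfispatial.geometry.tile_adjacency`. An EVT with at least one
    focal-subtype neighbour is "adjacent-to-focal" regardless of other
    neighbours (priority="focal"; priority="exclusive" instead drops EVTs
    with mixed neighbourhoods). EVTs with no DSC neighbour form the pool
    from which a control set depth-matched to the focal group is drawn.

    When the pool cannot cover every focal depth stratum, the matched
    comparison is restricted to the common support: ``focal_matched`` holds
    focal cells subsampled to the exact per-bin histogram of the matched
    control set, so the matched contrast compares identical depth
    distributions by construction.
    """
    focal_ids = dsc_cells.index[dsc_cells["subtype"] == focal_subtype]
    if len(focal_ids) == 0:
        raise ValueError(f"no cells of focal subtype {focal_subtype!r} in the section")
    pairs = pairs[pairs["cell_a"].isin(evt_cells.index) & pairs["cell_b"].isin(dsc_cells.index)]
    has_focal = pd.Index(pairs.loc[pairs["cell_b"].isin(focal_ids), "cell_a"].unique())
    has_any = pd.Index(pairs["cell_a"].unique())
    has_other = has_any.difference(has_focal)
    if priority == "focal":
        adjacent_focal = has_focal
    elif priority == "exclusive":
        other_ids = pd.Index(pairs.loc[~pairs["cell_b"].isin(focal_ids), "cell_a"].unique())
        adjacent_focal = has_focal.difference(other_ids)
    else:
        raise ValueError("priority must be 'focal' or 'exclusive'")
    pool = evt_cells.index.difference(has_any)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    match = geometry.depth_match(
        depths.reindex(adjacent_focal), depths.reindex(pool), bin_px=bin_px, seed=rng
    )
    # trim the focal group to the matched control's exact per-bin histogram
    ctrl_bins = np.floor(depths.reindex(match.matched_ids).to_numpy(float) / bin_px).astype(int)
    focal_bins = pd.Series(
        np.floor(depths.reindex(adjacent_focal).to_numpy(float) / bin_px).astype(int),
        index=adjacent_focal,
    )
    focal_matched: list = []
    for b, n_b in pd.Series(ctrl_bins).value_counts().sort_index().items():
        cand = focal_bins.index[focal_bins == b]
        pick = rng.choice(len(cand), size=min(int(n_b), len(cand)), replace=False)
        focal_matched.extend(cand[np.sort(pick)])
    focal_matched = pd.Index(focal_matched)
    balance_p = rank_sum_p(
        depths.reindex(focal_matched).to_numpy(float),
        depths.reindex(match.matched_ids).to_numpy(float),
    )
    return AdjacencyGroups(
        focal_subtype=focal_subtype,
        adjacent_focal=adjacent_focal,
        adjacent_other=has_other,
        matched_control=match.matched_ids,
        focal_matched=focal_matched,
        nonadjacent_pool=pool,
        depth_match_pvalue=balance_p,
    )


def contrast_iscores(
    groups: AdjacencyGroups,
    scores: pd.Series,
    min_group: int = 10,
) -> AdjacencyContrast:
    """Rank-sum contrasts of EVT iScores across adjacency groups.

    Tests focal-vs-other-adjacent and focal-vs-depth-matched-control, BH
    adjusted over this two-test family.
    """
    g = {
        "adjacent_focal": scores.reindex(groups.adjacent_focal).dropna(),
        "adjacent_other": scores.reindex(groups.adjacent_other).dropna(),
        "matched_control": scores.reindex(groups.matched_control).dropna(),
        "focal_matched": scores.reindex(groups.focal_matched).dropna(),
    }
    sizes = {k: len(v) for k, v in g.items()}
    small = {k: n for k, n in sizes.items() if n < min_group}
    if small:
        raise ValueError(f"undersized adjacency groups (need >= {min_group}): {sizes}")
    contrasts = {
        "focal_vs_other": rank_sum_p(g["adjacent_focal"], g["adjacent_other"]),
        "focal_vs_matched": rank_sum_p(g["focal_matched"], g["matched_control"]),
    }
    raw = pd.Series(contrasts, name="pvalue")
    adj = pd.Series(bh_adjust(raw.to_numpy()), index=raw.index, name="p_adjusted")
    return AdjacencyContrast(
        focal_subtype=groups.focal_subtype,
        group_medians={k: float(np.median(v)) for k, v in g.items()},
        group_n=sizes,
        pvalues=raw,
        p_adjusted=adj,
        depth_balance_pvalue=groups.depth_match_pvalue,
    )
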