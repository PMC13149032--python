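"""Toggle-switch classification of signed regulatory edges.

Trophoblast progenitors commit to one of two terminal lineages (EVT or SCT);
each lineage's transcription factors activate their own programme and repress
the alternative one. Given a signed TF->target edge list (inferred upstream
and consumed here as input) and the sets of lineage-upregulated TFs, edges
are classified into four categories by (TF lineage, coefficient sign):
EVT-activation, EVT-repression, SCT-activation, SCT-repression. Target-gene
expression per category is contrasted against a genome-wide background, and
target-set overlap of TFs shared between lineages is quantified with the
Jaccard index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData

from . import expr
from ._stats import bh_adjust, rank_sum_p

EDGE_COLUMNS = ["tf", "target", "coefficient", "lineage"]


def _check_edges(edges: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EDGE_COLUMNS if c not in edges.columns]
    if missing:
        raise ValueError(f"edge list is missing columns {missing}")
    if edges.duplicated(subset=["tf", "target", "lineage"]).any():
        raise ValueError("duplicate (tf, target, lineage) triples in the edge list")
    if not np.all(np.isfinite(edges["coefficient"].to_numpy(float))):
        raise ValueError("non-finite coefficients in the edge list")
    return edges


# ---------------------------------------------------------------------------
# lineage TF selection


@dataclass
class LineageTFs:
    by_lineage: dict  # lineage -> set of TFs
    overlap: set
    fdr: float


def select_lineage_tfs(
    deg_tables: dict, tf_universe, fdr: float = 0.01
) -> LineageTFs:
    """Lineage-specific upregulated TFs from composite DEG tables.

    ``deg_tables`` maps lineage name -> DEG table (vs the progenitor), as
    produced by :func:`mfispatial.signatures.composite_deg_score`. A TF is
    selected for a lineage when its FDR is below the threshold and its
    composite score is positive. TFs selected in several lineages are
    reported as the overlap set.
    """
    tf_universe = pd.Index(tf_universe)
    if len(tf_universe) == 0:
        raise ValueError("empty TF universe")
    by_lineage: dict[str, set] = {}
    for lineage, deg in deg_tables.items():
        sub = deg.reindex(tf_universe).dropna(subset=["fdr"])
        hits = sub.index[(sub["fdr"] < fdr) & (sub["score"] > 0)]
        by_lineage[lineage] = set(hits)
    overlap = set.intersection(*by_lineage.values()) if len(by_lineage) > 1 else set()
    return LineageTFs(by_lineage=by_lineage, overlap=overlap, fdr=fdr)


# ---------------------------------------------------------------------------
# edge filtering and classification


def filter_edges(edges: pd.DataFrame, c_min: float = 0.1) -> pd.DataFrame:
    """Retain edges with |coefficient| strictly above ``c_min``."""
    edges = _check_edges(edges)
    kept = edges[edges["coefficient"].abs() > c_min].copy()
    return kept


@dataclass
class ToggleClassification:
    edges: pd.DataFrame  # filtered edges + category, shared flag
    category_counts: dict
    n_dropped: int  # edges whose TF belongs to no lineage set


def classify_edges(
    edges: pd.DataFrame, lineage_tfs: dict | LineageTFs
) -> ToggleClassification:
    """Classify filtered edges into lineage activation/repression categories.

    An edge from a lineage-L TF with positive coefficient is "L-activation",
    with negative coefficient "L-repression". The edge's ``lineage`` column
    names the regulatory context it was inferred in; the TF must belong to
    that lineage's TF set, otherwise the edge is dropped (counted). TFs
    present in more than one lineage set are flagged ``shared``.
    """
    edges = _check_edges(edges)
    sets = lineage_tfs.by_lineage if isinstance(lineage_tfs, LineageTFs) else lineage_tfs
    rows = []
    n_dropped = 0
    membership = {
        tf: {lin for lin, tfs in sets.items() if tf in tfs}
        for tf in edges["tf"].unique()
    }
    for rec in edges.itertuples():
        lineages = membership[rec.tf]
        if rec.lineage not in lineages:
            n_dropped += 1
            continue
        kind = "activation" if rec.coefficient > 0 else "repression"
        rows.append(
            {
                "tf": rec.tf,
                "target": rec.target,
                "coefficient": rec.coefficient,
                "lineage": rec.lineage,
                "category": f"{rec.lineage}-{kind}",
                "shared_tf": len(lineages) > 1,
            }
        )
    out = pd.DataFrame(
        rows, columns=["tf", "target", "coefficient", "lineage", "category", "shared_tf"]
    )
    counts = out["category"].value_counts().to_dict()
    return ToggleClassification(edges=out, category_counts=counts, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# target contrasts and overlap


@dataclass
class TargetContrast:
    table: pd.DataFrame  # per (category, lineage): n targets, medians, p, p_adj
    background_size: dict


def target_contrast(
    classification: ToggleClassification,
    adata: AnnData,
    lineage_cells: dict,
    min_targets: int = 5,
    min_pct: float = 0.01,
    exclude_targets: bool = True,
) -> TargetContrast:
    """Contrast per-category target expression against genome background.

    For each edge category and each lineage, the distribution of per-gene
    mean log1p-normalized expression (within that lineage's cells) of the
    category's target genes is compared to the background of genes expressed
    in at least ``min_pct`` of the lineage's cells (targets excluded from the
    background by default). Rank-sum p-values are BH-adjusted over the whole
    family; ``direction`` is "up" when the target median exceeds the
    background median.
    """
    rows = []
    bg_sizes = {}
    means: dict[str, pd.Series] = {}
    eligible: dict[str, pd.Index] = {}
    for lineage, cells in lineage_cells.items():
        cells = pd.Index(cells)
        Xn = expr.lognorm(adata, cells=cells)
        means[lineage] = pd.Series(
            np.asarray(Xn.mean(axis=0)).ravel(), index=adata.var_names
        )
        pct = expr.pct_expressing(adata, cells)
        eligible[lineage] = adata.var_names[(pct >= min_pct).to_numpy()]
        bg_sizes[lineage] = int(len(eligible[lineage]))

    for category in sorted(classification.edges["category"].unique()):
        targets = pd.Index(
            classification.edges.loc[
                classification.edges["category"] == category, "target"
            ].unique()
        )
        targets = targets.intersection(adata.var_names)
        if len(targets) < min_targets:
            warnings.warn(
                f"category {category}: only {len(targets)} targets in the matrix; skipped"
            )
            continue
        for lineage in lineage_cells:
            bg = eligible[lineage].difference(targets) if exclude_targets else eligible[lineage]
            t_vals = means[lineage].reindex(targets).dropna().to_numpy()
            b_vals = means[lineage].reindex(bg).dropna().to_numpy()
            p = rank_sum_p(t_vals, b_vals)
            rows.append(
                {
                    "category": category,
                    "lineage": lineage,
                    "n_targets": len(t_vals),
                    "target_median": float(np.median(t_vals)),
                    "background_median": float(np.median(b_vals)),
                    "direction": "up" if np.median(t_vals) > np.median(b_vals) else "down",
                    "pvalue": p,
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adjusted"] = bh_adjust(table["pvalue"].to_numpy())
    return TargetContrast(table=table, background_size=bg_sizes)


def shared_tf_jaccard(classification: ToggleClassification, tf: str) -> float:
    """Jaccard overlap of a TF's target sets across the two lineage contexts.

    J = |targets_EVT intersect targets_SCT| / |targets_EVT union targets_SCT|
    (generally: over the two lineages the TF appears in).
    """
    edges = classification.edges
    mine = edges[edges["tf"] == tf]
    lineages = sorted(mine["lineage"].unique())
    if len(lineages) < 2:
        raise ValueError(
            f"TF {tf!r} has edges in {lineages or 'no'} lineage context(s); need two"
        )
    a = set(mine.loc[mine["lineage"] == lineages[0], "target"])
    b = set(mine.loc[mine["lineage"] == lineages[1], "target"])
    union = a | b
    return len(a & b) / len(union) if union else 0.0


# ---------------------------------------------------------------------------
# TSV I/O


def read_edges(path) -> pd.DataFrame:
    edges = pd.read_csv(path, sep="\t")
    return _check_edges(edges)


def write_edges(edges: pd.DataFrame, path) -> None:
    _check_edges(edges)[EDGE_COLUMNS].to_csv(path, sep="\t", index=False)
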