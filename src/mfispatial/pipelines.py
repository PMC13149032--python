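"""End-to-end experiment pipelines on synthetic tissue.

These functions wire the individual modules into the full analyses:
generate a section with planted truth, run an estimator chain, and report
the recovered quantities next to the planted ones. They are what the
example scripts and the reproduction script call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import (
    endothelium,
    expr,
    geometry,
    invasion,
    neighbors,
    signatures,
    synthetic,
    vessels,
)


@dataclass
class IscoreRecovery:
    model: invasion.InvasionModel
    n_selected: int
    sensitivity: float
    false_selections: int
    heldout_rho: float
    heldout_p: float
    n_test: int


def iscore_recovery(
    seed: int = 0,
    section_config: synthetic.SectionConfig | None = None,
    expression_config: synthetic.ExpressionConfig | None = None,
    k: int = 10,
    ratio: float = 0.5,
    cv_folds: int = 5,
) -> IscoreRecovery:
    """Full iScore chain on one synthetic section, scored against truth.

    Generates the section and expression, excludes vessel-associated EVTs,
    splits 1:1, builds k-cell pseudobulk windows, fits the cross-validated
    LASSO and validates on held-out single cells. Sensitivity and false
    selections compare the selected genes with the planted invasion program.
    """
    scfg = section_config or synthetic.SectionConfig(seed=seed)
    ecfg = expression_config or synthetic.ExpressionConfig(seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        section, truth = synthetic.generate_section(scfg)
        adata, truth = synthetic.generate_expression(section, ecfg, truth)
        distances = geometry.compute_distances(section)
        depths = distances["d_interface_px"].abs()
        eligible = invasion.eligible_evts(section.cells, distances)
        train, test = invasion.split_train_test(eligible, ratio=ratio, seed=seed)
        X_train = expr.lognorm_df(adata, cells=train)
        X_test = expr.lognorm_df(adata, cells=test)
        windows = invasion.build_windows(depths.loc[train], X_train, k=k)
        model = invasion.fit_model(windows, cv_folds=cv_folds, seed=seed)
        report = invasion.validate(model, X_test, depths.loc[test], train_ids=train)
    planted = set(truth.expression["invasion_genes"])
    selected = set(model.selected.index)
    return IscoreRecovery(
        model=model,
        n_selected=len(selected),
        sensitivity=len(planted & selected) / max(len(planted), 1),
        false_selections=len(selected - planted),
        heldout_rho=report.rho,
        heldout_p=report.pvalue,
        n_test=report.n,
    )


@dataclass
class Dsc4Analysis:
    contrast: neighbors.AdjacencyContrast
    groups: neighbors.AdjacencyGroups
    n_suppressed_truth: int


def dsc4_contrast(
    seed: int = 0,
    section_config: synthetic.SectionConfig | None = None,
    expression_config: synthetic.ExpressionConfig | None = None,
    tile_px: float = 50.0,
    k_tiles: int = 5,
    suppression_delta: float = -1.0,
) -> Dsc4Analysis:
    """Planted-suppression recovery: iScores of EVTs adjacent to DSC4.

    Plants a strong local suppression (``suppression_delta`` log-mean within
    the suppression radius of DSC4 cells), trains the iScore model on the
    same section, scores every EVT, and runs the adjacency contrast (focal
    vs other-DSC-adjacent, focal vs depth-matched non-adjacent).
    """
    scfg = section_config or synthetic.SectionConfig(seed=seed)
    ecfg = expression_config or synthetic.ExpressionConfig(
        seed=seed, suppression_delta=suppression_delta
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        section, truth = synthetic.generate_section(scfg)
        adata, truth = synthetic.generate_expression(section, ecfg, truth)
        distances = geometry.compute_distances(section)
        depths = distances["d_interface_px"].abs()
        eligible = invasion.eligible_evts(section.cells, distances)
        train, _ = invasion.split_train_test(eligible, seed=seed)
        X_train = expr.lognorm_df(adata, cells=train)
        windows = invasion.build_windows(depths.loc[train], X_train, k=10)
        model = invasion.fit_model(windows, seed=seed)

        evts = section.cells.index[section.cells.cell_type == "EVT"]
        X_all = expr.lognorm_df(adata, cells=evts)
        scores = invasion.score_cells(model, X_all)
        dsc = section.cells[section.cells.cell_type == "DSC"]
        pairs = geometry.tile_adjacency(
            section.cells, tile_px=tile_px, k_tiles=k_tiles,
            between=(evts, dsc.index),
        )
        groups = neighbors.assign_adjacency_groups(
            section.cells.loc[evts], dsc, pairs, depths, seed=seed
        )
        contrast = neighbors.contrast_iscores(groups, scores["iscore"])
    return Dsc4Analysis(
        contrast=contrast,
        groups=groups,
        n_suppressed_truth=len(truth.expression["suppressed_evt_ids"]),
    )


def null_enrichment_section(seed: int, n_vessels: int = 8, n_evt: int = 800):
    """Section with uniformly placed EVTs (no vessel enrichment, no gradient)."""
    cfg = synthetic.SectionConfig(
        width_px=4000.0, height_px=4000.0, interface_y_px=1000.0,
        interface_amplitude_px=100.0,
        n_vessels=n_vessels, vessel_radius_px=120.0, vessel_margin_px=250.0,
        n_evt=n_evt, n_dsc=0, n_ec=0, n_immune=0, n_vct=0, n_sct=0,
        evt_depth_decay_px=None, evt_vessel_factor=1.0, seed=seed,
    )
    section, _ = synthetic.generate_section(cfg)
    return section


def enriched_section(seed: int, n_vessels: int = 62, n_evt: int = 3000,
                     factor: float = 3.0):
    """Wide section with a planted vessel-annulus EVT enrichment factor."""
    cfg = synthetic.SectionConfig(
        width_px=12000.0, height_px=7000.0, interface_y_px=1200.0,
        interface_amplitude_px=100.0, interface_period_px=3000.0,
        n_vessels=n_vessels, vessel_radius_px=120.0, vessel_margin_px=250.0,
        n_evt=n_evt, n_dsc=0, n_ec=0, n_immune=0, n_vct=0, n_sct=0,
        evt_depth_decay_px=None, evt_vessel_factor=factor,
        evt_vessel_zone_px=100.0, seed=seed,
    )
    section, _ = synthetic.generate_section(cfg)
    return section


def vessel_enrichment_pvalue(section, seed: int = 0,
                             spec: vessels.RegionSpec | None = None) -> float:
    """Pooled vessel-vs-null EVT density test on one section."""
    spec = spec or vessels.RegionSpec(seed=seed)
    distances = geometry.compute_distances(section)
    return vessels.run_enrichment(section, distances, spec).pvalue
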