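"""Reading and writing tissue-section bundles, plus cell-level QC.

A section bundle is a directory of plain-text files:

* ``cells.tsv`` -- cell_id, x_px, y_px, cell_type, subtype[, compartment]
* ``landmarks.geojson`` -- FeatureCollection; the interface is a LineString
  with ``role: interface`` (property ``maternal_side``: above/below); vessels
  are Polygons with ``role: vessel`` and an integer ``vessel_id``.
* ``matrix.mtx`` + ``genes.tsv`` (optional) -- MatrixMarket coordinate
  format, 1-based indices, genes x cells with columns ordered as cells.tsv;
  genes.tsv is a two-column TSV (id, name).
* ``truth.json`` (optional) -- planted ground truth for synthetic sections.

Coordinates are 0.5-um pixels, origin lower-left, y increasing upward (the
GeoJSON properties block records this).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData
from shapely.geometry import LineString, Polygon, mapping, shape

from . import expr

CELL_COLUMNS = ["x_px", "y_px", "cell_type", "subtype"]


@dataclass
class TissueSection:
    """Per-cell spatial universe of one tissue section.

    ``cells`` is indexed by unique cell_id with columns x_px, y_px,
    cell_type, subtype and optionally compartment. ``expression`` (optional)
    is an AnnData whose obs_names are a subset of (usually equal to) the cell
    index.
    """

    section_id: str
    cells: pd.DataFrame
    interface: LineString
    maternal_side: str = "above"
    vessels: dict[int, Polygon] = field(default_factory=dict)
    expression: AnnData | None = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.cells.index.is_unique:
            dupes = self.cells.index[self.cells.index.duplicated()].unique()
            raise ValueError(f"duplicate cell_ids: {list(dupes)[:5]}")
        xy = self.cells[["x_px", "y_px"]].to_numpy(float)
        if not np.all(np.isfinite(xy)):
            raise ValueError("non-finite cell coordinates")
        if len(self.interface.coords) < 2:
            raise ValueError("interface polyline needs >= 2 vertices")
        for vid, poly in self.vessels.items():
            if not poly.is_valid or poly.is_empty:
                raise ValueError(f"vessel {vid}: polygon is not closed/simple")

    def with_cells(self, cells: pd.DataFrame) -> "TissueSection":
        expression = self.expression
        if expression is not None:
            keep = expression.obs_names.isin(cells.index)
            expression = expression[keep].copy()
        return TissueSection(
            self.section_id, cells, self.interface, self.maternal_side,
            dict(self.vessels), expression,
        )


# ---------------------------------------------------------------------------
# bundle writing / loading


def write_section(section: TissueSection, path: str | Path) -> Path:
    """Write a section bundle; cells.tsv rows are sorted by cell_id."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cells = section.cells.sort_index()
    cells.to_csv(path / "cells.tsv", sep="\t", index_label="cell_id", float_format="%.6f")

    features = [
        {
            "type": "Feature",
            "geometry": mapping(section.interface),
            "properties": {"role": "interface", "maternal_side": section.maternal_side},
        }
    ]
    for vid in sorted(section.vessels):
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(section.vessels[vid]),
                "properties": {"role": "vessel", "vessel_id": int(vid)},
            }
        )
    collection = {
        "type": "FeatureCollection",
        "properties": {
            "section_id": section.section_id,
            "units": "pixel (0.5 um)",
            "origin": "lower-left, y up",
        },
        "features": features,
    }
    (path / "landmarks.geojson").write_text(json.dumps(collection, indent=1))

    if section.expression is not None:
        adata = section.expression[cells.index[cells.index.isin(section.expression.obs_names)].to_numpy()]
        X = expr.counts_matrix(adata)
        scipy.io.mmwrite(str(path / "matrix.mtx"), X.T.tocoo())  # genes x cells
        pd.DataFrame({"gene_id": adata.var_names, "gene_name": adata.var_names}).to_csv(
            path / "genes.tsv", sep="\t", index=False, header=False
        )
    return path


def _load_landmarks(path: Path):
    collection = json.loads(path.read_text())
    interface = None
    maternal_side = "above"
    vessels: dict[int, Polygon] = {}
    for i, feat in enumerate(collection.get("features", [])):
        role = feat.get("properties", {}).get("role")
        geom = feat.get("geometry", {})
        if role == "interface":
            if len(geom.get("coordinates", [])) < 2:
                raise ValueError(
                    f"landmark feature {i} (interface): polyline has fewer than 2 vertices"
                )
            interface = shape(geom)
            maternal_side = feat["properties"].get("maternal_side", "above")
        elif role == "vessel":
            poly = shape(geom)
            if not poly.is_valid:
                raise ValueError(f"landmark feature {i} (vessel): polygon not closed/simple")
            vessels[int(feat["properties"]["vessel_id"])] = poly
    if interface is None:
        raise ValueError(f"{path}: no feature with role 'interface'")
    return interface, maternal_side, vessels


def load_section(path: str | Path) -> TissueSection:
    """Load a section bundle written by :func:`write_section`."""
    path = Path(path)
    cells_path = path / "cells.tsv"
    lm_path = path / "landmarks.geojson"
    for p in (cells_path, lm_path):
        if not p.exists():
            raise FileNotFoundError(f"section bundle is missing {p.name} ({p})")
    cells = pd.read_csv(cells_path, sep="\t", index_col="cell_id")
    if cells.index.duplicated().any():
        dupes = cells.index[cells.index.duplicated()].unique()
        raise ValueError(f"{cells_path}: duplicate cell_ids {list(dupes)[:5]}")
    interface, maternal_side, vessels = _load_landmarks(lm_path)

    expression = None
    mtx_path = path / "matrix.mtx"
    if mtx_path.exists():
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)
        gene_ids = genes.iloc[:, 0].astype(str).tolist()
        M = scipy.io.mmread(str(mtx_path))  # genes x cells, 1-based on disk
        X = sp.csr_matrix(M.T)
        if X.shape != (len(cells), len(gene_ids)):
            raise ValueError(
                f"matrix.mtx shape {M.shape} does not match "
                f"{len(gene_ids)} genes x {len(cells)} cells"
            )
        expression = AnnData(
            X=X,
            obs=pd.DataFrame(index=cells.index.astype(str)),
            var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")),
        )
    return TissueSection(
        section_id=path.name,
        cells=cells,
        interface=interface,
        maternal_side=maternal_side,
        vessels=vessels,
        expression=expression,
    )


# ---------------------------------------------------------------------------
# QC filtering


@dataclass
class QCThresholds:
    """Cell-level QC cutoffs.

    Exclusion is strict (<, >): cells with fewer than ``min_genes`` detected
    genes, more than ``max_mids`` total transcripts, or mitochondrial fraction
    above ``max_mito_frac`` are removed; boundary values are retained.
    ``max_genes`` is an optional separate cap on detected genes.
    """

    min_genes: int = 100
    max_mids: int = 10_000
    max_mito_frac: float = 0.20
    max_genes: int | None = None
    mito_prefix: str = "MT-"

    def __post_init__(self):
        if self.min_genes < 0:
            raise ValueError("min_genes must be >= 0")
        if not (0.0 <= self.max_mito_frac <= 1.0):
            raise ValueError("max_mito_frac must be in [0, 1]")


@dataclass
class QCReport:
    n_input: int
    n_retained: int
    removed: dict


def filter_cells(
    section: TissueSection, thresholds: QCThresholds | None = None
) -> tuple[TissueSection, QCReport]:
    """Apply cell-level QC; returns the filtered section and a removal report.

    Requires attached expression. The per-criterion removal counts are not
    mutually exclusive (a cell can fail several rules).
    """
    thresholds = thresholds or QCThresholds()
    adata = section.expression
    if adata is None:
        raise ValueError("filter_cells requires expression attached to the section")
    totals = expr.cell_totals(adata)
    ngenes = expr.genes_detected(adata)
    mito_genes = adata.var_names[adata.var_names.str.startswith(thresholds.mito_prefix)]
    if len(mito_genes):
        Xm = expr.counts_matrix(adata[:, mito_genes.to_numpy()])
        mito = np.asarray(Xm.sum(axis=1), dtype=float).ravel()
    else:
        mito = np.zeros(adata.n_obs)
    tot = totals.to_numpy(dtype=float)
    mito_frac = pd.Series(
        np.divide(mito, tot, out=np.zeros_like(mito), where=tot > 0),
        index=adata.obs_names,
    )

    low_complexity = ngenes < thresholds.min_genes
    too_many_mids = totals > thresholds.max_mids
    high_mito = mito_frac > thresholds.max_mito_frac
    fail = low_complexity | too_many_mids | high_mito
    removed = {
        "low_complexity": int(low_complexity.sum()),
        "excessive_mids": int(too_many_mids.sum()),
        "high_mito": int(high_mito.sum()),
    }
    if thresholds.max_genes is not None:
        too_many_genes = ngenes > thresholds.max_genes
        fail |= too_many_genes
        removed["excessive_genes"] = int(too_many_genes.sum())

    keep_ids = adata.obs_names[~fail.reindex(adata.obs_names).to_numpy()]
    kept_cells = section.cells.loc[section.cells.index.isin(keep_ids) | ~section.cells.index.isin(adata.obs_names)]
    out = section.with_cells(kept_cells)
    report = QCReport(n_input=int(adata.n_obs), n_retained=int(len(keep_ids)), removed=removed)
    return out, report
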