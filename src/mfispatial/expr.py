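"""Expression-matrix helpers.

Counts live in an :class:`anndata.AnnData` (cells = obs, genes = var, sparse
``X``). Everything downstream of raw counts works on library-size normalized,
log1p-transformed values produced here. Normalization scales each cell to a
common target total (the median total of the cells being normalized unless a
fixed target is given), so the target is always computed from the cell subset
actually handed in -- a training subset never borrows statistics from held-out
cells.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData


def counts_matrix(adata: AnnData) -> sp.csr_matrix:
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    return X.tocsr()


def cell_totals(adata: AnnData) -> pd.Series:
    """Total transcript count (MIDs) per cell."""
    X = counts_matrix(adata)
    return pd.Series(np.asarray(X.sum(axis=1)).ravel(), index=adata.obs_names)


def genes_detected(adata: AnnData) -> pd.Series:
    X = counts_matrix(adata)
    return pd.Series(X.getnnz(axis=1), index=adata.obs_names)


def lognorm(
    adata: AnnData,
    cells: Iterable[str] | None = None,
    target_sum: float | None = None,
) -> sp.csr_matrix:
    """Library-size normalize then log1p.

    Each cell's counts are scaled to ``target_sum`` total (default: median
    total over the selected cells) and transformed with log1p. Returns a CSR
    matrix over the selected cells in the given order, all genes.
    """
    if cells is not None:
        cells = pd.Index(cells)
        sub = adata[cells.to_numpy()]
    else:
        sub = adata
    X = counts_matrix(sub).astype(np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if target_sum is None:
        nonzero = totals[totals > 0]
        target_sum = float(np.median(nonzero)) if nonzero.size else 1.0
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals), where=totals > 0)
    X = sp.diags(scale) @ X
    X.data = np.log1p(X.data)
    return X.tocsr()


def lognorm_df(
    adata: AnnData,
    genes: Sequence[str] | None = None,
    cells: Iterable[str] | None = None,
    target_sum: float | None = None,
) -> pd.DataFrame:
    """Dense cells x genes DataFrame of log1p-normalized expression."""
    cells_idx = pd.Index(cells) if cells is not None else adata.obs_names
    X = lognorm(adata, cells=cells_idx, target_sum=target_sum)
    if genes is not None:
        genes = pd.Index(genes)
        missing = genes.difference(adata.var_names)
        if len(missing):
            raise KeyError(f"genes absent from expression matrix: {list(missing)[:10]}")
        col = adata.var_names.get_indexer(genes)
        X = X[:, col]
    else:
        genes = adata.var_names
    return pd.DataFrame(np.asarray(X.todense()), index=cells_idx, columns=genes)


def pct_expressing(adata: AnnData, cells: Iterable[str]) -> pd.Series:
    """Fraction of the given cells with a nonzero count, per gene."""
    cells = pd.Index(cells)
    X = counts_matrix(adata[cells.to_numpy()])
    frac = X.getnnz(axis=0) / max(len(cells), 1)
    return pd.Series(frac, index=adata.var_names)
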