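"""Composite differential-expression scores and bin-controlled module scores.

The composite DEG score for gene g between groups a and b is

    S_g = log2FC_g * |dPct_g|

with log2FC_g = log2((mu_a + 1)/(mu_b + 1)) on library-size normalized means
and dPct_g the difference in the percentage of expressing cells (percentage
points, in [-100, 100]). The magnitude of dPct weights the fold change, and
the direction of S comes from the fold change alone, which makes S exactly
antisymmetric under group swap (a raw product of the two signed factors
would be symmetric, ranking strongly depleted genes alongside enriched
ones). Significance
comes from a per-gene two-sided Wilcoxon rank-sum test with BH correction.

Module scores (e.g. the endothelium-like score of vessel-adjacent EVTs) are
computed against expression-matched control genes: genes are ranked by mean
expression into equal-frequency bins and each signature gene contributes
control genes drawn from its own bin, so library-size and detection effects
cancel in the signature-minus-control difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import stats

from . import expr
from ._stats import bh_adjust, spearman


def composite_deg_score(
    adata: AnnData,
    group_a,
    group_b,
    target_sum: float | None = None,
) -> pd.DataFrame:
    """Per-gene composite DEG table for two disjoint cell groups.

    Columns: log2fc, delta_pct, score, pvalue, fdr. Both groups need >= 2
    cells and must not overlap.
    """
    group_a, group_b = pd.Index(group_a), pd.Index(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need at least 2 cells")
    if len(group_a.intersection(group_b)):
        raise ValueError("groups overlap")
    both = group_a.append(group_b)
    Xn = expr.lognorm(adata, cells=both, target_sum=target_sum)
    lin = Xn.copy()
    lin.data = np.expm1(lin.data)  # back to normalized linear scale
    na = len(group_a)
    mu_a = np.asarray(lin[:na].mean(axis=0)).ravel()
    mu_b = np.asarray(lin[na:].mean(axis=0)).ravel()
    log2fc = np.log2((mu_a + 1.0) / (mu_b + 1.0))
    pct_a = 100.0 * expr.pct_expressing(adata, group_a).to_numpy()
    pct_b = 100.0 * expr.pct_expressing(adata, group_b).to_numpy()
    delta_pct = pct_a - pct_b

    A = np.asarray(Xn[:na].todense())
    B = np.asarray(Xn[na:].todense())
    res = stats.mannwhitneyu(A, B, alternative="two-sided", method="asymptotic", axis=0)
    pvals = np.asarray(res.pvalue, dtype=float)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "delta_pct": delta_pct,
            "score": log2fc * np.abs(delta_pct),
            "pvalue": pvals,
            "fdr": bh_adjust(pvals),
        },
        index=adata.var_names,
    )


def top_markers(deg: pd.DataFrame, n: int = 100, fdr: float = 0.05) -> list[str]:
    """Top-n genes by composite score among FDR-significant genes.

    Ties on the score break by larger |log2fc|, then gene id. Returns all
    eligible genes (with a warning) when fewer than n pass the FDR cut.
    """
    eligible = deg[deg["fdr"] < fdr].copy()
    eligible["_abs_fc"] = eligible["log2fc"].abs()
    eligible["_gene"] = eligible.index
    eligible = eligible.sort_values(
        ["score", "_abs_fc", "_gene"], ascending=[False, False, True], kind="mergesort"
    )
    if len(eligible) < n:
        warnings.warn(f"only {len(eligible)} genes pass FDR < {fdr}; returning all")
    return eligible.index[:n].tolist()


@dataclass
class ModuleScore:
    """Per-cell signature score with its expression-matched control pool."""

    scores: pd.Series
    signature: list
    controls: dict  # signature gene -> list of control genes
    n_bins: int
    n_controls: int


def module_score(
    adata: AnnData,
    signature,
    n_bins: int = 25,
    n_controls: int = 100,
    seed: int | np.random.Generator = 0,
    cells=None,
    target_sum: float | None = None,
) -> ModuleScore:
    """Bin-controlled module score on log1p-normalized expression.

    Genes are ranked by mean expression (over all cells of ``adata``) into
    ``n_bins`` equal-frequency bins; each signature gene draws ``n_controls``
    control genes without replacement from its bin, excluding all signature
    genes. Per cell, score = mean(signature) - mean(pooled controls).

    If ``adata.layers["lognorm"]`` is present it is used as the normalized
    log1p matrix directly; otherwise counts in ``adata.X`` are normalized
    here.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n_controls < 1:
        raise ValueError("n_controls must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    signature = pd.Index(signature)
    missing = signature.difference(adata.var_names)
    if len(missing):
        raise KeyError(f"signature genes absent from the matrix: {list(missing)}")

    if "lognorm" in adata.layers:
        import scipy.sparse as sp

        L = adata.layers["lognorm"]
        Xn = sp.csr_matrix(L) if not sp.issparse(L) else L.tocsr()
    else:
        Xn = expr.lognorm(adata, target_sum=target_sum)
    means = np.asarray(Xn.mean(axis=0)).ravel()
    order = np.argsort(means, kind="stable")
    bin_of = np.empty(len(means), dtype=int)
    bin_of[order] = np.floor(
        np.arange(len(means)) * n_bins / len(means)
    ).astype(int)
    gene_pos = pd.Series(np.arange(adata.n_vars), index=adata.var_names)
    sig_pos = gene_pos[signature].to_numpy()
    in_sig = np.zeros(adata.n_vars, dtype=bool)
    in_sig[sig_pos] = True

    controls: dict[str, list[str]] = {}
    control_pos: list[int] = []
    for g, p in zip(signature, sig_pos):
        candidates = np.flatnonzero((bin_of == bin_of[p]) & ~in_sig)
        if len(candidates) == 0:
            raise ValueError(f"no control candidates available for signature gene {g}")
        take = min(n_controls, len(candidates))
        if take < n_controls:
            warnings.warn(
                f"signature gene {g}: only {take} control candidates in its bin"
            )
        pick = candidates[rng.choice(len(candidates), size=take, replace=False)]
        controls[str(g)] = [str(adata.var_names[i]) for i in pick]
        control_pos.extend(pick.tolist())

    cells_idx = pd.Index(cells) if cells is not None else adata.obs_names
    row = adata.obs_names.get_indexer(cells_idx)
    sig_mean = np.asarray(Xn[row][:, sig_pos].mean(axis=1)).ravel()
    ctl_mean = np.asarray(Xn[row][:, np.asarray(control_pos)].mean(axis=1)).ravel()
    scores = pd.Series(sig_mean - ctl_mean, index=cells_idx, name="module_score")
    return ModuleScore(
        scores=scores,
        signature=signature.tolist(),
        controls=controls,
        n_bins=n_bins,
        n_controls=n_controls,
    )


@dataclass
class CorrelationReport:
    rho: float
    pvalue: float
    n: int


def score_vs_distance(
    scores: pd.Series, distances: pd.Series, cells=None
) -> CorrelationReport:
    """Spearman correlation between a per-cell score and a distance covariate."""
    if cells is not None:
        cells = pd.Index(cells)
    else:
        cells = scores.index.intersection(distances.index)
    s = scores.reindex(cells)
    d = distances.reindex(cells)
    ok = s.notna() & d.notna()
    if int(ok.sum()) < 10:
        raise ValueError(f"need at least 10 cells, got {int(ok.sum())}")
    rho, p = spearman(s[ok].to_numpy(), d[ok].to_numpy())
    return CorrelationReport(rho=rho, pvalue=p, n=int(ok.sum()))
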