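"""The iScore framework: sparse-regression prediction of EVT invasiveness.

EVTs not associated with spiral arteries are split 1:1 into training and
test sets. Training cells are sorted by decidual depth |d_interface| and
averaged in consecutive windows of k cells (pseudobulk) to reduce sparsity;
an L1-penalized (LASSO) regression of window depth on standardized window
expression selects a sparse gene panel. The signed coefficients define the
invasiveness score of a single cell,

    iScore = sum_g beta_g * (x_g - mean_g) / sd_g,

computed on log1p-normalized expression and normalized to mean 0 / sd 1
within each tissue section. Positive coefficients mark pro-invasive genes,
negative coefficients anti-invasive ones. Validation is the Spearman
correlation between held-out single-cell iScores and observed depth.

``lasso_fit`` uses the objective 0.5*||y - Xb||^2 + lam*||b||_1 (so on an
orthonormal design the solution is exact soft-thresholding of the OLS
coefficients); :func:`fit_model` selects lam by k-fold cross-validated MSE.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

from ._stats import rank_sum_p, spearman


# ---------------------------------------------------------------------------
# cell selection and splitting


def eligible_evts(
    cells: pd.DataFrame,
    distances: pd.DataFrame,
    exclusion_radius_px: float = 200.0,
    excluded_subtypes=("eEVT", "pEVT"),
    evt_label: str = "EVT",
) -> pd.Index:
    """Maternal-side EVTs not associated with spiral arteries.

    Vessel association = |d_vessel| <= exclusion_radius_px or a vessel
    subtype label (endovascular / perivascular).
    """
    mask = (cells["cell_type"] == evt_label) & (
        distances["compartment"].reindex(cells.index) == "maternal"
    )
    if "subtype" in cells.columns:
        mask &= ~cells["subtype"].isin(excluded_subtypes)
    if "d_vessel_px" in distances.columns:
        dv = distances["d_vessel_px"].reindex(cells.index).abs()
        mask &= ~(dv <= exclusion_radius_px).fillna(False)
    return cells.index[mask]


def split_train_test(ids, ratio: float = 0.5, seed: int = 0) -> tuple[pd.Index, pd.Index]:
    """Random disjoint partition of cell ids (train fraction = ratio)."""
    ids = pd.Index(ids)
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(ratio * len(ids)))
    return ids[np.sort(perm[:n_train])], ids[np.sort(perm[n_train:])]


# ---------------------------------------------------------------------------
# pseudobulk windows


@dataclass
class Windows:
    """Depth-contiguous pseudobulk windows of k cells each."""

    X: pd.DataFrame  # window x gene mean expression
    depth: pd.Series  # window mean depth (px)
    members: list  # list of member-id lists
    n_dropped: int


def build_windows(depths: pd.Series, X: pd.DataFrame, k: int = 10) -> Windows:
    """Group k depth-adjacent cells into averaged pseudobulk profiles.

    Cells are sorted by depth (ties by cell id); consecutive groups of k are
    averaged and the trailing remainder (< k cells) is dropped.
    """
    if k < 2:
        raise ValueError("window size k must be >= 2")
    order = (
        pd.DataFrame({"d": depths})
        .assign(_id=lambda df: df.index)
        .sort_values(["d", "_id"], kind="mergesort")
        .index
    )
    n_windows = len(order) // k
    n_dropped = len(order) - n_windows * k
    if n_dropped:
        warnings.warn(f"build_windows: dropped trailing remainder of {n_dropped} cells")
    rowsX, rowsd, members = [], [], []
    Xs = X.loc[order]
    ds = depths.loc[order]
    for w in range(n_windows):
        sl = slice(w * k, (w + 1) * k)
        rowsX.append(Xs.iloc[sl].mean(axis=0))
        rowsd.append(float(ds.iloc[sl].mean()))
        members.append(list(order[sl]))
    widx = pd.Index([f"W{w:05d}" for w in range(n_windows)], name="window")
    return Windows(
        X=pd.DataFrame(rowsX, index=widx),
        depth=pd.Series(rowsd, index=widx, name="depth"),
        members=members,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# LASSO fitting


def lasso_fit(
    X: np.ndarray, y: np.ndarray, lam: float, fit_intercept: bool = True
) -> tuple[np.ndarray, float]:
    """Minimize 0.5*||y - Xb - b0||^2 + lam*||b||_1.

    lam = 0 falls back to ordinary least squares (minimum-norm solution).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if lam == 0:
        if fit_intercept:
            Xd = np.column_stack([np.ones(len(X)), X])
            coef, *_ = np.linalg.lstsq(Xd, y, rcond=None)
            return coef[1:], float(coef[0])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return coef, 0.0
    model = Lasso(
        alpha=lam / len(y), fit_intercept=fit_intercept, max_iter=100_000, tol=1e-12
    )
    model.fit(X, y)
    return model.coef_.copy(), float(model.intercept_) if fit_intercept else 0.0


@dataclass
class InvasionModel:
    """Fitted iScore model: standardization + sparse coefficient vector."""

    features: list
    mean: np.ndarray
    sd: np.ndarray
    lam: float
    beta: np.ndarray
    intercept: float
    dropped_features: list
    cv: pd.DataFrame | None
    path_nnz: list
    seed: int

    @property
    def selected(self) -> pd.DataFrame:
        """Nonzero-coefficient genes with their signs (+: pro-invasive)."""
        nz = np.flatnonzero(self.beta)
        return pd.DataFrame(
            {
                "gene": [self.features[i] for i in nz],
                "coefficient": self.beta[nz],
                "effect": np.where(self.beta[nz] > 0, "pro-invasive", "anti-invasive"),
            }
        ).set_index("gene")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "features": list(map(str, self.features)),
            "mean": [float(v) for v in self.mean],
            "sd": [float(v) for v in self.sd],
            "lambda": float(self.lam),
            "beta": [float(v) for v in self.beta],
            "intercept": float(self.intercept),
            "dropped_features": list(map(str, self.dropped_features)),
            "path_nnz": [int(v) for v in self.path_nnz],
            "seed": int(self.seed),
        }
        text = json.dumps(payload, sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "InvasionModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            features=d["features"],
            mean=np.asarray(d["mean"]),
            sd=np.asarray(d["sd"]),
            lam=d["lambda"],
            beta=np.asarray(d["beta"]),
            intercept=d["intercept"],
            dropped_features=d["dropped_features"],
            cv=None,
            path_nnz=d["path_nnz"],
            seed=d["seed"],
        )


def _lambda_grid(Xs: np.ndarray, y: np.ndarray, n_lambdas: int = 30) -> np.ndarray:
    yc = y - y.mean()
    lam_max = np.max(np.abs(Xs.T @ yc))
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * 1e-2, n_lambdas)


def fit_model(
    windows: Windows,
    lambda_grid=None,
    cv_folds: int = 5,
    seed: int = 0,
    selection: str = "cv-margin",
    cv_margin: float = 0.10,
) -> InvasionModel:
    """Cross-validated LASSO of window depth on standardized window expression.

    Features are standardized with training statistics only; zero-variance
    features are dropped and recorded. The penalty is chosen from the
    ``cv_folds``-fold cross-validated MSE curve:

    * ``selection="cv-margin"`` (default): the largest lam whose CV error is
      within ``cv_margin`` (relative) of the minimum -- a deterministic
      parsimony rule that trades at most 10% predictive loss for a sparser
      panel and does not depend on the noisy fold-to-fold SE estimate;
    * ``selection="1se"``: the classical one-standard-error rule;
    * ``selection="min"``: the CV minimum (densest panels).

    The model is refit on all training windows at the chosen lam;
    ``path_nnz`` records the number of selected genes along the (descending)
    lam grid of those final fits.
    """
    X = windows.X
    y = windows.depth.to_numpy(float)
    if len(X) < cv_folds:
        raise ValueError(f"need at least cv_folds={cv_folds} windows, got {len(X)}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = X.columns[~keep].tolist()
    if not keep.any():
        raise ValueError("all features have zero variance in the training windows")
    feats = X.columns[keep]
    Xs = ((X[feats] - mean[feats]) / sd[feats]).to_numpy(float)

    grid = np.sort(np.asarray(
        lambda_grid if lambda_grid is not None else _lambda_grid(Xs, y)
    , dtype=float))[::-1]

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    mse = np.zeros((len(grid), cv_folds))
    for f, (tr, te) in enumerate(kf.split(Xs)):
        model = Lasso(alpha=1.0, max_iter=20_000, tol=1e-4, warm_start=True)
        for i, lam in enumerate(grid):
            model.alpha = lam / len(tr)
            model.fit(Xs[tr], y[tr])
            pred = model.predict(Xs[te])
            mse[i, f] = np.mean((pred - y[te]) ** 2)
    cv_mean = mse.mean(axis=1)
    cv_se = mse.std(axis=1, ddof=1) / np.sqrt(cv_folds)
    i_min = int(np.argmin(cv_mean))
    if selection == "cv-margin":
        ok = np.flatnonzero(cv_mean <= cv_mean[i_min] * (1.0 + cv_margin))
        i_pick = int(ok[0])  # grid is descending in lam: first hit = largest lam
    elif selection == "1se":
        ok = np.flatnonzero(cv_mean <= cv_mean[i_min] + cv_se[i_min])
        i_pick = int(ok[0])
    elif selection == "min":
        i_pick = i_min
    else:
        raise ValueError("selection must be 'cv-margin', '1se' or 'min'")
    lam_pick = float(grid[i_pick])

    # final path on all windows (records sparsity along the grid) + chosen fit
    path_nnz = []
    beta_pick, int_pick = None, None
    model = Lasso(alpha=1.0, max_iter=100_000, tol=1e-8, warm_start=True)
    for i, lam in enumerate(grid):
        model.alpha = lam / len(y)
        model.fit(Xs, y)
        path_nnz.append(int(np.count_nonzero(model.coef_)))
        if i == i_pick:
            beta_pick = model.coef_.copy()
            int_pick = float(model.intercept_)

    cv_table = pd.DataFrame({"lambda": grid, "cv_mse": cv_mean, "cv_se": cv_se})
    return InvasionModel(
        features=feats.tolist(),
        mean=mean[feats].to_numpy(float),
        sd=sd[feats].to_numpy(float),
        lam=lam_pick,
        beta=beta_pick,
        intercept=int_pick,
        dropped_features=dropped,
        cv=cv_table,
        path_nnz=path_nnz,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# scoring and validation


def score_cells(
    model: InvasionModel,
    X: pd.DataFrame,
    sections: pd.Series | None = None,
    standardization: str = "train",
) -> pd.DataFrame:
    """Per-cell raw and section-normalized iScores.

    ``X`` is a cells x genes table of log1p-normalized expression covering at
    least 50% of the model's selected genes (missing selected genes are
    dropped with a warning). ``standardization`` is "train" (use the model's
    training means/sds) or "own" (z-score within ``X`` itself, as for
    independent external datasets).
    """
    sel = model.selected
    present = [g for g in sel.index if g in X.columns]
    if len(present) < 0.5 * len(sel):
        raise ValueError(
            f"only {len(present)}/{len(sel)} selected genes present (< 50%)"
        )
    if len(present) < len(sel):
        warnings.warn(
            f"{len(sel) - len(present)} selected genes missing; scored on {len(present)}"
        )
    pos = [model.features.index(g) for g in present]
    V = X[present].to_numpy(float)
    if standardization == "train":
        mu, sdv = model.mean[pos], model.sd[pos]
    elif standardization == "own":
        mu = V.mean(axis=0)
        sdv = V.std(axis=0, ddof=0)
    else:
        raise ValueError("standardization must be 'train' or 'own'")
    sdv = np.where(sdv > 0, sdv, 1.0)
    coef = sel.loc[present, "coefficient"].to_numpy(float)
    raw = ((V - mu) / sdv) @ coef
    out = pd.DataFrame({"iscore_raw": raw}, index=X.index)
    out["section"] = sections.reindex(X.index) if sections is not None else "section0"
    normed = np.full(len(out), np.nan)
    for sec, grp in out.groupby("section"):
        v = grp["iscore_raw"].to_numpy()
        if len(v) < 2 or v.std(ddof=0) == 0:
            warnings.warn(f"section {sec}: < 2 cells or zero variance; normalization skipped")
            normed[out.index.get_indexer(grp.index)] = v - (v.mean() if len(v) else 0.0)
        else:
            normed[out.index.get_indexer(grp.index)] = (v - v.mean()) / v.std(ddof=0)
    out["iscore"] = normed
    return out


@dataclass
class ValidationReport:
    rho: float
    pvalue: float
    n: int


def validate(
    model: InvasionModel,
    X_test: pd.DataFrame,
    depths_test: pd.Series,
    train_ids=None,
) -> ValidationReport:
    """Spearman correlation of held-out single-cell iScores with depth."""
    if train_ids is not None and len(pd.Index(train_ids).intersection(X_test.index)):
        raise ValueError("test cells overlap the training set")
    scores = score_cells(model, X_test)["iscore_raw"]
    d = depths_test.reindex(X_test.index)
    rho, p = spearman(scores.to_numpy(), d.to_numpy())
    return ValidationReport(rho=rho, pvalue=p, n=len(scores))


@dataclass
class BenchmarkReport:
    group_medians: dict
    pvalue: float
    direction: str
    n: dict


def benchmark_external(
    model: InvasionModel,
    X_external: pd.DataFrame,
    groups: pd.Series,
) -> BenchmarkReport:
    """Apply the trained model to an external log1p-normalized matrix.

    Expression is z-scored per gene within the external dataset, iScores are
    computed with the trained coefficients, and the two groups are compared
    with a two-sided rank-sum test.
    """
    labels = pd.unique(groups.dropna())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {list(labels)}")
    scores = score_cells(model, X_external, standardization="own")["iscore_raw"]
    a = scores[groups.reindex(scores.index) == labels[0]].to_numpy()
    b = scores[groups.reindex(scores.index) == labels[1]].to_numpy()
    p = rank_sum_p(a, b)
    med = {str(labels[0]): float(np.median(a)), str(labels[1]): float(np.median(b))}
    direction = (
        f"{labels[0]} > {labels[1]}" if med[str(labels[0])] > med[str(labels[1])]
        else f"{labels[0]} < {labels[1]}"
    )
    return BenchmarkReport(
        group_medians=med, pvalue=p, direction=direction,
        n={str(labels[0]): int(a.size), str(labels[1]): int(b.size)},
    )
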