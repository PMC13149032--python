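"""Arterial endothelial remodelling states from PDE3A x VIM quadrants.

During spiral-artery remodelling, arterial endothelium passes through four
sequential states distinguished by co-expression of PDE3A and VIM:

* caEC (PDE3A hi, VIM hi) -- canonical arterial endothelium on the wall,
* R0   (PDE3A hi, VIM low) -- primed, still wall-adherent,
* R1   (PDE3A low, VIM low) -- losing arterial identity, displaced,
* R2   (PDE3A low, VIM hi) -- detached, apoptotic terminal state.

This module assigns states by thresholding the two markers ("hi" means
value >= threshold), quantifies marker separability with bootstrap AUROC,
and validates the spatial ordering of states by their absolute distance to
the vessel wall.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from ._stats import bh_adjust, rank_sum_p

STATES = ("caEC", "R0", "R1", "R2")
_QUADRANT = {
    (True, True): "caEC",
    (True, False): "R0",
    (False, False): "R1",
    (False, True): "R2",
}


@dataclass
class StateThresholds:
    tau_pde3a: float
    tau_vim: float
    method: str = "supplied"

    def __post_init__(self):
        if not (np.isfinite(self.tau_pde3a) and np.isfinite(self.tau_vim)):
            raise ValueError("thresholds must be finite")


def median_thresholds(markers: pd.DataFrame) -> StateThresholds:
    """Per-marker median over the given endothelial cells."""
    _require_markers(markers)
    return StateThresholds(
        tau_pde3a=float(markers["PDE3A"].median()),
        tau_vim=float(markers["VIM"].median()),
        method="median",
    )


def percentile_thresholds(markers: pd.DataFrame, q: float = 50.0) -> StateThresholds:
    _require_markers(markers)
    return StateThresholds(
        tau_pde3a=float(np.percentile(markers["PDE3A"], q)),
        tau_vim=float(np.percentile(markers["VIM"], q)),
        method=f"percentile-{q:g}",
    )


def _require_markers(markers: pd.DataFrame) -> None:
    for m in ("PDE3A", "VIM"):
        if m not in markers.columns:
            raise KeyError(f"marker {m!r} missing from the expression table")


def classify_states(
    markers: pd.DataFrame, thresholds: StateThresholds
) -> pd.DataFrame:
    """Assign each endothelial cell a state by the quadrant rule.

    ``markers`` has columns PDE3A and VIM (log1p-normalized values). The
    rule is total: every cell gets exactly one state; values exactly at a
    threshold count as "hi".
    """
    _require_markers(markers)
    hi_p = markers["PDE3A"].to_numpy(float) >= thresholds.tau_pde3a
    hi_v = markers["VIM"].to_numpy(float) >= thresholds.tau_vim
    state = np.where(
        hi_p, np.where(hi_v, "caEC", "R0"), np.where(hi_v, "R2", "R1")
    )
    return pd.DataFrame(
        {"state": state, "pde3a_hi": hi_p, "vim_hi": hi_v}, index=markers.index
    )


@dataclass
class AurocReport:
    mean: float
    sd: float
    replicates: np.ndarray
    contrast: tuple
    marker: str


def bootstrap_auroc(
    values: pd.Series,
    labels: pd.Series,
    positive,
    B: int = 10,
    seed: int | np.random.Generator = 0,
) -> AurocReport:
    """Bootstrap AUROC of one marker for a two-state contrast.

    Cells are resampled with replacement ``B`` times; each replicate's AUROC
    is the rank-based (midrank-tied) estimator for ``positive`` vs the other
    label present.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    classes = pd.unique(lab)
    if len(classes) != 2 or positive not in classes:
        raise ValueError(
            f"contrast needs exactly two classes including {positive!r}; got {list(classes)}"
        )
    y = lab == positive
    if y.all() or not y.any():
        raise ValueError("one class of the contrast is absent")
    reps = np.empty(B)
    for b in range(B):
        while True:
            idx = rng.integers(0, len(v), len(v))
            if y[idx].any() and not y[idx].all():
                break
        reps[b] = roc_auc_score(y[idx], v[idx])
    other = classes[classes != positive][0]
    return AurocReport(
        mean=float(reps.mean()),
        sd=float(reps.std(ddof=1)),
        replicates=reps,
        contrast=(positive, other),
        marker=str(values.name) if values.name else "",
    )


@dataclass
class StateDistanceProfile:
    summary: pd.DataFrame  # per state: n, median |d_V|
    tests: pd.DataFrame  # pairwise rank-sum p, BH-adjusted


def state_distance_profile(
    states: pd.Series, abs_dv: pd.Series
) -> StateDistanceProfile:
    """Per-state wall-distance summaries with BH-corrected pairwise tests.

    States with zero cells are excluded (with a warning); the remodelling
    expectation is median |d_V| non-decreasing along caEC -> R0 -> R1 -> R2.
    """
    import warnings

    df = pd.DataFrame({"state": states, "abs_dv": abs_dv}).dropna()
    present = [s for s in STATES if (df["state"] == s).any()]
    for s in STATES:
        if s not in present:
            warnings.warn(f"state {s} has no cells; excluded from the profile")
    groups = {s: df.loc[df["state"] == s, "abs_dv"].to_numpy() for s in present}
    summary = pd.DataFrame(
        {
            "n": [len(groups[s]) for s in present],
            "median_abs_dv": [float(np.median(groups[s])) for s in present],
        },
        index=pd.Index(present, name="state"),
    )
    pairs = list(combinations(present, 2))
    pvals = [rank_sum_p(groups[a], groups[b]) for a, b in pairs]
    tests = pd.DataFrame(
        {
            "state_a": [a for a, _ in pairs],
            "state_b": [b for _, b in pairs],
            "pvalue": pvals,
            "p_adjusted": bh_adjust(pvals) if pairs else [],
        }
    )
    return StateDistanceProfile(summary=summary, tests=tests)
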