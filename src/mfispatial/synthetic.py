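"""Synthetic maternal-fetal interface sections with planted ground truth.

The generator emulates the geometry and expression structure of a basal-plate
section profiled at single-cell resolution: a sinusoid-perturbed interface
splits the section into a fetal compartment (villi: VCT/SCT) and a maternal
decidua containing stromal, immune and endothelial cells plus invading EVTs;
circular spiral-artery cross-sections sit wholly inside the decidua. Counts
are negative binomial with planted programs whose parameters are recorded in
a :class:`GroundTruth` so that every downstream estimator can be scored
against what was actually simulated:

* EVT placement density decays exponentially with decidual depth and is
  enriched by a constant factor inside a perivascular zone;
* invasion genes change log-mean linearly with depth in EVTs;
* endothelium-like (mimicry) genes are elevated in EVTs near vessel walls,
  with a plateau at the wall and exponential decay beyond it;
* endothelial PDE3A/VIM log-means are set per remodelling state
  (caEC/R0/R1/R2), and states are placed at increasing wall offsets;
* EVTs within a given radius of a DSC4 cell have their invasion genes
  shifted by a suppression term.

All generators are pure functions of (config, seed): the same seed yields
byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import shapely
from anndata import AnnData
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Point

from . import geometry
from .io import TissueSection

EC_STATES = ("caEC", "R0", "R1", "R2")
GRN_CATEGORIES = ("EVT-activation", "EVT-repression", "SCT-activation", "SCT-repression")


# ---------------------------------------------------------------------------
# configs


@dataclass
class SectionConfig:
    """Geometry and cell-placement parameters (lengths in 0.5-um pixels)."""

    width_px: float = 6000.0
    height_px: float = 6000.0
    interface_y_px: float = 2000.0
    interface_amplitude_px: float = 200.0
    interface_period_px: float = 2000.0
    interface_vertex_spacing_px: float = 50.0
    n_vessels: int = 3
    vessel_radius_px: float = 150.0
    vessel_margin_px: float = 300.0  # clearance of vessels from interface/borders
    n_evt: int = 4000
    n_dsc: int = 150  # subtype-annotated DSCs only; kept sparse so that
    # EVTs outside any DSC neighbourhood exist (the depth-matched control pool)
    n_ec: int = 800
    n_immune: int = 800
    n_vct: int = 1000
    n_sct: int = 1000
    evt_depth_decay_px: float | None = 1000.0  # None = uniform over depth
    evt_vessel_factor: float = 3.0  # density multiplier in the perivascular zone
    evt_vessel_zone_px: float = 100.0
    dsc4_depth_scale_px: float = 400.0
    dsc4_n_clusters: int = 5  # DSC4 cells cluster near anchoring-villus termini
    dsc4_cluster_sd_px: float = 150.0
    dsc_mix: tuple = (0.2, 0.2, 0.2, 0.2, 0.2)  # DSC0..DSC4
    ec_state_mix: tuple = (0.4, 0.2, 0.2, 0.2)  # caEC, R0, R1, R2
    ec_state_offsets_px: dict = field(
        default_factory=lambda: {"caEC": 5.0, "R0": 5.0, "R1": 30.0, "R2": 120.0}
    )
    seed: int = 0

    def __post_init__(self):
        for name in (
            "width_px", "height_px", "interface_period_px",
            "vessel_radius_px", "interface_vertex_spacing_px",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("n_vessels", "n_evt", "n_dsc", "n_ec", "n_immune", "n_vct", "n_sct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.evt_depth_decay_px is not None and self.evt_depth_decay_px <= 0:
            raise ValueError("evt_depth_decay_px must be > 0 or None")


@dataclass
class ExpressionConfig:
    """Planted expression programs (log-mean scale; counts ~ NB(theta, mu))."""

    n_genes: int = 3000
    baseline_log_mean: float = -0.5
    baseline_log_sd: float = 1.0
    nb_theta: float = 5.0
    n_mito_genes: int = 10
    mito_baseline: float = 1.5
    # depth-linear invasion program (EVTs, maternal depth |d_I| in px)
    n_invasion_genes: int = 40
    invasion_gene_baseline: float = 1.5
    invasion_slope_range: tuple = (0.5, 0.9)  # log-mean change per 1000 px, sign random
    # program genes are transcriptionally bursty (their own NB dispersion);
    # the extra gene-level noise matches how noisy real program genes are and
    # keeps the 40 depth-driven features statistically distinguishable
    program_dispersion: float = 0.5
    # anti-invasive (depth-declining) genes start high at the interface so
    # their decline stays measurable across the full decidual depth
    anti_invasive_span_px: float = 2500.0
    # high, spatially flat housekeeping stratum: gives expression-matched
    # control pools for module scoring at the planted programs' level
    n_housekeeping_genes: int = 150
    housekeeping_baseline: float = 2.2
    # endothelium-like (mimicry) program
    n_mimicry_genes: int = 100
    mimicry_gene_baseline: float = 2.2
    mimicry_amplitude: float = 0.8  # log-mean shift at the vessel wall
    mimicry_zone_px: float = 100.0  # full-amplitude plateau around the wall
    mimicry_decay_px: float = 200.0
    ec_enrichment: float = 1.5  # extra log-mean of mimicry genes in endothelium
    # PDE3A x VIM quadrant means per endothelial state (log-mean)
    state_marker_means: dict = field(
        default_factory=lambda: {
            "caEC": (2.5, 2.5),  # (PDE3A, VIM)
            "R0": (2.5, 0.0),
            "R1": (0.0, 0.0),
            "R2": (0.0, 2.5),
        }
    )
    # local suppression of the invasion program near DSC4 (log-mean shift of
    # depth-increasing genes; depth-decreasing genes shift by -delta). The
    # default is a modest everyday effect; detection experiments plant
    # stronger values explicitly.
    suppression_delta: float = -0.3
    suppression_radius_px: float = 250.0
    seed: int = 0

    def __post_init__(self):
        if self.nb_theta <= 0:
            raise ValueError("nb_theta must be > 0")
        if self.suppression_radius_px < 0:
            raise ValueError("suppression_radius_px must be >= 0")
        planted = (
            self.n_mito_genes + self.n_invasion_genes + self.n_mimicry_genes
            + self.n_housekeeping_genes + 2
        )
        if self.n_genes < planted:
            raise ValueError("n_genes too small for the planted gene sets")


@dataclass
class GroundTruth:
    """Planted parameters of a synthetic dataset (JSON-serializable)."""

    section: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)
    grn: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(**d)


# ---------------------------------------------------------------------------
# section generation


def _interface_line(config: SectionConfig) -> LineString:
    xs = np.arange(0.0, config.width_px + 1e-9, config.interface_vertex_spacing_px)
    if xs[-1] < config.width_px:
        xs = np.append(xs, config.width_px)
    ys = config.interface_y_px + config.interface_amplitude_px * np.sin(
        2 * np.pi * xs / config.interface_period_px
    )
    return LineString(np.column_stack([xs, ys]))


def _place_vessels(config: SectionConfig, iface: LineString, rng: np.random.Generator):
    r = config.vessel_radius_px
    m = config.vessel_margin_px
    y_top_of_iface = config.interface_y_px + config.interface_amplitude_px
    lo_x, hi_x = r + m, config.width_px - r - m
    lo_y, hi_y = y_top_of_iface + r + m, config.height_px - r - m
    if config.n_vessels and (lo_x >= hi_x or lo_y >= hi_y):
        raise ValueError("section too small to place vessels: placement error")
    centers: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 500 * max(config.n_vessels, 1)
    while len(centers) < config.n_vessels:
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {config.n_vessels} non-overlapping vessels: placement error"
            )
        attempts += 1
        cx = rng.uniform(lo_x, hi_x)
        cy = rng.uniform(lo_y, hi_y)
        if all((cx - ox) ** 2 + (cy - oy) ** 2 >= (2 * r + 100.0) ** 2 for ox, oy in centers):
            centers.append((cx, cy))
    vessels = {
        vid: Point(c).buffer(r, quad_segs=64) for vid, c in enumerate(centers)
    }
    return vessels, centers


def _truncated_exponential(rng, scale: float | None, upper: np.ndarray) -> np.ndarray:
    """Draw from Exp(scale) truncated to [0, upper) (uniform if scale is None)."""
    u = rng.uniform(size=upper.shape)
    if scale is None:
        return u * upper
    return -scale * np.log1p(-u * (1.0 - np.exp(-upper / scale)))


def _sample_maternal(
    n: int,
    config: SectionConfig,
    iface: LineString,
    rng: np.random.Generator,
    depth_scale: float | None,
    vessels: dict,
    vessel_factor: float = 1.0,
    zone_px: float = 0.0,
    exclude_lumen: bool = True,
) -> np.ndarray:
    """Rejection-sample maternal positions with depth- and vessel-dependent density."""
    out = np.empty((0, 2))
    while len(out) < n:
        batch = max(2 * (n - len(out)), 256)
        x = rng.uniform(0.0, config.width_px, batch)
        y_if = geometry.interface_y_at(iface, x)
        avail = config.height_px - y_if
        depth = _truncated_exponential(rng, depth_scale, avail)
        y = y_if + depth
        pts = np.column_stack([x, y])
        keep = np.ones(batch, dtype=bool)
        if vessels:
            inside_any = np.zeros(batch, dtype=bool)
            near_wall = np.zeros(batch, dtype=bool)
            for poly in vessels.values():
                inside = shapely.contains_xy(poly, x, y)
                inside_any |= inside
                if vessel_factor != 1.0 and zone_px > 0:
                    d = shapely.distance(shapely.points(x, y), poly.exterior)
                    near_wall |= d <= zone_px
            if exclude_lumen:
                keep &= ~inside_any
            if vessel_factor != 1.0 and zone_px > 0:
                w = np.where(near_wall, vessel_factor, 1.0)
                keep &= rng.uniform(size=batch) < w / max(vessel_factor, 1.0)
        out = np.vstack([out, pts[keep]])
    return out[:n]


def generate_section(config: SectionConfig) -> tuple[TissueSection, GroundTruth]:
    """Generate a synthetic section with planted geometry.

    Returns the section (cells + landmarks, no expression yet) and the
    ground truth recording per-cell planted labels.
    """
    rng = np.random.default_rng(config.seed)
    iface = _interface_line(config)
    vessels, centers = _place_vessels(config, iface, rng) if config.n_vessels else ({}, [])

    rows: list[pd.DataFrame] = []

    def add(xy: np.ndarray, cell_type: str, subtype: np.ndarray | str, compartment: str):
        if len(xy) == 0:
            return
        sub = np.repeat(subtype, len(xy)) if isinstance(subtype, str) else subtype
        rows.append(
            pd.DataFrame(
                {
                    "x_px": xy[:, 0],
                    "y_px": xy[:, 1],
                    "cell_type": cell_type,
                    "subtype": sub,
                    "compartment": compartment,
                }
            )
        )

    # --- EVTs: depth-decaying density, enriched in the perivascular zone, lumen allowed
    evt_xy = _sample_maternal(
        config.n_evt, config, iface, rng,
        depth_scale=config.evt_depth_decay_px,
        vessels=vessels,
        vessel_factor=config.evt_vessel_factor,
        zone_px=config.evt_vessel_zone_px,
        exclude_lumen=False,
    )
    if len(evt_xy) and vessels:
        dv = geometry.signed_distance_to_vessel(
            pd.DataFrame({"x_px": evt_xy[:, 0], "y_px": evt_xy[:, 1]}), vessels
        )["d_vessel_px"].to_numpy()
        subtype = np.where(
            dv > 0, "eEVT",
            np.where((dv >= -config.evt_vessel_zone_px) & (rng.uniform(size=len(dv)) < 0.6),
                     "pEVT", "iEVT"),
        )
    else:
        subtype = np.repeat("iEVT", len(evt_xy))
    add(evt_xy, "EVT", subtype, geometry.MATERNAL)

    # --- DSC subtypes: DSC0-3 uniform over the decidua; DSC4 superficial and
    # clustered (patches near anchoring-villus termini rather than a blanket)
    n_per = np.floor(np.asarray(config.dsc_mix) * config.n_dsc).astype(int)
    n_per[0] += config.n_dsc - n_per.sum()
    for i, n_sub in enumerate(n_per[:4]):
        xy = _sample_maternal(int(n_sub), config, iface, rng, None, vessels)
        add(xy, "DSC", f"DSC{i}", geometry.MATERNAL)
    n_dsc4 = int(n_per[4])
    if n_dsc4:
        k = max(config.dsc4_n_clusters, 1)
        cx = rng.uniform(0.05 * config.width_px, 0.95 * config.width_px, k)
        cd = _truncated_exponential(
            rng, config.dsc4_depth_scale_px, np.full(k, config.height_px / 3)
        )
        which = rng.integers(0, k, n_dsc4)
        x4 = cx[which] + rng.normal(0.0, config.dsc4_cluster_sd_px, n_dsc4)
        d4 = np.abs(cd[which] + rng.normal(0.0, config.dsc4_cluster_sd_px / 2, n_dsc4))
        x4 = np.clip(x4, 0.0, config.width_px)
        y4 = geometry.interface_y_at(iface, x4) + d4
        y4 = np.minimum(y4, config.height_px)
        add(np.column_stack([x4, y4]), "DSC", "DSC4", geometry.MATERNAL)

    # --- endothelium: on/near vessel walls with state-dependent outward offsets
    if config.n_ec:
        if not vessels:
            raise ValueError("endothelial cells require at least one vessel")
        n_states = np.floor(np.asarray(config.ec_state_mix) * config.n_ec).astype(int)
        n_states[0] += config.n_ec - n_states.sum()
        r = config.vessel_radius_px
        for state, n_state in zip(EC_STATES, n_states):
            if n_state == 0:
                continue
            mu = config.ec_state_offsets_px[state]
            offset = np.abs(rng.normal(mu, 0.25 * mu + 2.0, int(n_state)))
            offset = np.minimum(offset, config.vessel_margin_px - 20.0)
            which = rng.integers(0, len(centers), int(n_state))
            ang = rng.uniform(0, 2 * np.pi, int(n_state))
            cx = np.array([centers[i][0] for i in which])
            cy = np.array([centers[i][1] for i in which])
            xy = np.column_stack(
                [cx + (r + offset) * np.cos(ang), cy + (r + offset) * np.sin(ang)]
            )
            add(xy, "EC", state, geometry.MATERNAL)

    # --- immune cells (dNK / macrophage), uniform over the decidua
    n_dnk = int(round(0.6 * config.n_immune))
    add(_sample_maternal(n_dnk, config, iface, rng, None, vessels), "dNK", "dNK", geometry.MATERNAL)
    add(_sample_maternal(config.n_immune - n_dnk, config, iface, rng, None, vessels),
        "M", "M", geometry.MATERNAL)

    # --- fetal compartment: VCT / SCT uniform below the interface
    for n_f, t in ((config.n_vct, "VCT"), (config.n_sct, "SCT")):
        if n_f == 0:
            continue
        got = np.empty((0, 2))
        while len(got) < n_f:
            x = rng.uniform(0.0, config.width_px, 2 * n_f)
            y = rng.uniform(0.0, config.interface_y_px + config.interface_amplitude_px, 2 * n_f)
            keep = y < geometry.interface_y_at(iface, x)
            got = np.vstack([got, np.column_stack([x, y])[keep]])
        add(got[:n_f], t, t, geometry.FETAL)

    if rows:
        cells = pd.concat(rows, ignore_index=True)
    else:
        cells = pd.DataFrame(columns=["x_px", "y_px", "cell_type", "subtype", "compartment"])
    cells.index = pd.Index([f"C{i:06d}" for i in range(len(cells))], name="cell_id")

    section = TissueSection(
        section_id=f"synthetic-{config.seed}",
        cells=cells,
        interface=iface,
        maternal_side="above",
        vessels=vessels,
    )
    truth = GroundTruth(
        section={
            "seed": config.seed,
            "ec_states": cells.loc[cells.cell_type == "EC", "subtype"].to_dict(),
            "ec_state_offsets_px": dict(config.ec_state_offsets_px),
            "evt_depth_decay_px": config.evt_depth_decay_px,
            "evt_vessel_factor": config.evt_vessel_factor,
            "vessel_centers": [list(c) for c in centers],
            "vessel_radius_px": config.vessel_radius_px,
        }
    )
    return section, truth


# ---------------------------------------------------------------------------
# expression generation


def gene_universe(config: ExpressionConfig) -> pd.Index:
    n_generic = config.n_genes - 2 - config.n_mito_genes
    names = (
        ["PDE3A", "VIM"]
        + [f"MT-G{i:02d}" for i in range(config.n_mito_genes)]
        + [f"G{i:04d}" for i in range(n_generic)]
    )
    return pd.Index(names, name="gene_id")


def generate_expression(
    section: TissueSection,
    config: ExpressionConfig,
    truth: GroundTruth | None = None,
) -> tuple[AnnData, GroundTruth]:
    """Simulate NB counts with the planted programs and attach them to the section.

    The depth covariate uses |d_interface| on the maternal side only; fetal
    cells receive no invasion term. Mimicry and suppression terms require
    vessels / DSC4 cells and are skipped (with truth recording the empty
    sets) when the section has none.
    """
    rng = np.random.default_rng(config.seed)
    genes = gene_universe(config)
    G = len(genes)
    cells = section.cells
    n = len(cells)

    # per-gene baselines
    base = np.empty(G)
    base[0] = base[1] = 0.0  # PDE3A, VIM outside endothelium
    base[2 : 2 + config.n_mito_genes] = config.mito_baseline
    n_generic = G - 2 - config.n_mito_genes
    base[2 + config.n_mito_genes :] = rng.normal(
        config.baseline_log_mean, config.baseline_log_sd, n_generic
    )

    generic_pos = np.arange(2 + config.n_mito_genes, G)
    n_pick = (
        config.n_invasion_genes + config.n_mimicry_genes + config.n_housekeeping_genes
    )
    picked = rng.choice(generic_pos, size=n_pick, replace=False)
    inv_pos = np.sort(picked[: config.n_invasion_genes])
    mim_pos = np.sort(
        picked[config.n_invasion_genes : config.n_invasion_genes + config.n_mimicry_genes]
    )
    hk_pos = np.sort(picked[config.n_invasion_genes + config.n_mimicry_genes :])
    base[inv_pos] = config.invasion_gene_baseline
    base[mim_pos] = config.mimicry_gene_baseline
    base[hk_pos] = config.housekeeping_baseline

    lo, hi = config.invasion_slope_range
    slopes = rng.uniform(lo, hi, config.n_invasion_genes)
    signs = np.where(rng.uniform(size=config.n_invasion_genes) < 0.5, 1.0, -1.0)
    slopes *= signs
    # anti-invasive genes are trophoblast program genes: inside EVTs they
    # start high at the interface (so their decline stays measurable at
    # depth); outside EVTs they sit at the plain baseline
    anti_invasive_boost = np.where(
        slopes < 0, np.abs(slopes) * config.anti_invasive_span_px / 1000.0, 0.0
    )

    # spatial covariates
    d_if = geometry.signed_distance_to_interface(cells, section.interface, section.maternal_side)
    depth = np.clip(d_if["d_interface_px"].to_numpy(), 0.0, None)  # maternal depth only
    if section.vessels:
        abs_dv = np.abs(
            geometry.signed_distance_to_vessel(cells, section.vessels)["d_vessel_px"].to_numpy()
        )
    else:
        abs_dv = None

    is_evt = (cells["cell_type"] == "EVT").to_numpy()
    is_ec = (cells["cell_type"] == "EC").to_numpy()
    dsc4_xy = cells.loc[cells["subtype"] == "DSC4", ["x_px", "y_px"]].to_numpy(float)
    suppressed = np.zeros(n, dtype=bool)
    if len(dsc4_xy) and config.suppression_radius_px > 0 and is_evt.any():
        tree = cKDTree(dsc4_xy)
        evt_xy = cells.loc[is_evt, ["x_px", "y_px"]].to_numpy(float)
        dist, _ = tree.query(evt_xy, k=1)
        suppressed[np.flatnonzero(is_evt)[dist <= config.suppression_radius_px]] = True

    # assemble log-means
    logmu = np.tile(base, (n, 1)).astype(np.float64)
    if is_evt.any():
        rows = np.flatnonzero(is_evt)
        logmu[np.ix_(rows, inv_pos)] += (
            np.outer(depth[rows] / 1000.0, slopes) + anti_invasive_boost[None, :]
        )
        if abs_dv is not None and config.n_mimicry_genes:
            prof = np.minimum(
                1.0,
                np.exp(-(np.maximum(abs_dv[rows] - config.mimicry_zone_px, 0.0))
                       / config.mimicry_decay_px),
            )
            logmu[np.ix_(rows, mim_pos)] += config.mimicry_amplitude * prof[:, None]
        srows = np.flatnonzero(suppressed)
        if len(srows):
            # suppression moves the cell down the invasion program: genes that
            # rise with depth are shifted by delta, genes that fall with depth
            # by -delta (a uniform shift of all genes would cancel in any
            # signed invasiveness readout)
            program_sign = np.where(slopes >= 0, 1.0, -1.0)
            logmu[np.ix_(srows, inv_pos)] += config.suppression_delta * program_sign
    if is_ec.any():
        rows = np.flatnonzero(is_ec)
        logmu[np.ix_(rows, mim_pos)] += config.ec_enrichment
        states = cells.loc[is_ec, "subtype"].to_numpy()
        for state, (m_pde, m_vim) in config.state_marker_means.items():
            srows = rows[states == state]
            logmu[srows, 0] = m_pde
            logmu[srows, 1] = m_vim

    mu = np.exp(logmu)
    theta = np.full(G, config.nb_theta)
    theta[inv_pos] = config.program_dispersion
    p = theta / (theta + mu)
    counts = rng.negative_binomial(np.tile(theta, (n, 1)), p).astype(np.int32)
    X = sp.csr_matrix(counts)

    adata = AnnData(
        X=X,
        obs=cells[["cell_type", "subtype"]].copy(),
        var=pd.DataFrame(index=genes),
    )
    section.expression = adata

    out = truth if truth is not None else GroundTruth()
    out.expression = {
        "seed": config.seed,
        "invasion_genes": {genes[i]: float(s) for i, s in zip(inv_pos, slopes)},
        "mimicry_genes": [genes[i] for i in mim_pos],
        "mimicry_amplitude": config.mimicry_amplitude,
        "ec_enriched_genes": [genes[i] for i in mim_pos],
        "suppressed_evt_ids": cells.index[suppressed].tolist(),
        "suppression_delta": config.suppression_delta,
        "suppression_radius_px": config.suppression_radius_px,
        "state_marker_means": {k: list(v) for k, v in config.state_marker_means.items()},
        "nb_theta": config.nb_theta,
        "program_dispersion": config.program_dispersion,
    }
    return adata, out


# ---------------------------------------------------------------------------
# GRN generation


def generate_grn(
    n_tfs: int = 40,
    n_targets: int = 120,
    n_edges: int = 524,
    sign_mix: tuple = (224 / 524, 18 / 524, 234 / 524, 48 / 524),
    below_frac: float = 0.2,
    c_min: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Signed TF->target edge list with known categories.

    ``sign_mix`` gives the proportions of the four categories
    (EVT-activation, EVT-repression, SCT-activation, SCT-repression); the
    default mirrors the observed four-category composition of the trophoblast
    toggle network. ``below_frac`` of the edges get |coefficient| below the
    filter threshold ``c_min`` (they should be removed by edge filtering);
    all magnitudes are bounded away from the threshold.
    """
    mix = np.asarray(sign_mix, dtype=float)
    if mix.min() < 0 or abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("sign_mix proportions must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)

    n_cat = np.floor(mix * n_edges).astype(int)
    n_cat[int(np.argmax(mix))] += n_edges - n_cat.sum()
    evt_tfs = [f"TF-EVT-{i:03d}" for i in range(n_tfs // 2)]
    sct_tfs = [f"TF-SCT-{i:03d}" for i in range(n_tfs - n_tfs // 2)]
    targets = [f"TG-{i:04d}" for i in range(n_targets)]

    records = []
    used = set()
    for cat, n_c in zip(GRN_CATEGORIES, n_cat):
        lineage = "EVT" if cat.startswith("EVT") else "SCT"
        sign = 1.0 if cat.endswith("activation") else -1.0
        pool = evt_tfs if lineage == "EVT" else sct_tfs
        for _ in range(int(n_c)):
            for _attempt in range(10_000):
                tf = pool[rng.integers(0, len(pool))]
                tg = targets[rng.integers(0, len(targets))]
                if (tf, tg, lineage) not in used:
                    used.add((tf, tg, lineage))
                    break
            else:
                raise ValueError("could not draw enough unique (tf, target, lineage) triples")
            below = rng.uniform() < below_frac
            mag = rng.uniform(0.01, c_min - 0.005) if below else rng.uniform(c_min + 0.005, 0.6)
            records.append(
                {
                    "tf": tf,
                    "target": tg,
                    "coefficient": sign * mag,
                    "lineage": lineage,
                    "category": cat,
                    "passes_filter": not below,
                }
            )
    df = pd.DataFrame.from_records(records)
    edges = df[["tf", "target", "coefficient", "lineage"]].copy()
    truth = GroundTruth(
        grn={
            "seed": seed,
            "categories": df["category"].tolist(),
            "passes_filter": df["passes_filter"].tolist(),
            "evt_tfs": evt_tfs,
            "sct_tfs": sct_tfs,
            "c_min": c_min,
        }
    )
    return edges, truth
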