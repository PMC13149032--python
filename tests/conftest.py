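"""Shared fixtures: one full synthetic tissue generated once per session."""

import warnings

import numpy as np
import pytest

import mfispatial as mfi
from mfispatial import expr, geometry


@pytest.fixture(scope="session")
def tissue():
    """Default synthetic section with expression, distances and truth."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cfg = mfi.SectionConfig(seed=5)
        section, truth = mfi.generate_section(cfg)
        adata, truth = mfi.generate_expression(section, mfi.ExpressionConfig(seed=5), truth)
        # cache the normalized layer for tests that score many signatures
        adata.layers["lognorm"] = expr.lognorm(adata)
    distances = geometry.compute_distances(section)
    return {
        "config": cfg,
        "section": section,
        "truth": truth,
        "adata": adata,
        "distances": distances,
        "depths": distances["d_interface_px"].abs(),
    }


@pytest.fixture(scope="session")
def small_section():
    """Tiny section without expression for fast geometry tests."""
    cfg = mfi.SectionConfig(
        n_evt=400, n_dsc=60, n_ec=120, n_immune=50, n_vct=50, n_sct=50,
        n_vessels=2, seed=9,
    )
    section, truth = mfi.generate_section(cfg)
    return section, truth


def rng(seed=0):
    return np.random.default_rng(seed)
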