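"""Geometry: signed distances, binning, tile adjacency, depth matching."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Point, Polygon

from mfispatial import geometry


def brute_force_polyline_distance(cells_xy, coords, spacing=0.01):
    """Oracle: min distance to the polyline densely resampled at `spacing` px."""
    samples = []
    coords = np.asarray(coords, float)
    for a, b in zip(coords[:-1], coords[1:]):
        seg_len = np.hypot(*(b - a))
        n = max(int(np.ceil(seg_len / spacing)), 1)
        t = np.linspace(0.0, 1.0, n + 1)[:, None]
        samples.append(a + t * (b - a))
    samples = np.vstack(samples)
    out = np.empty(len(cells_xy))
    for i in range(0, len(cells_xy), 64):  # chunked to bound memory
        chunk = cells_xy[i : i + 64]
        d2 = ((chunk[:, None, :] - samples[None, :, :]) ** 2).sum(axis=2)
        out[i : i + 64] = np.sqrt(d2.min(axis=1))
    return out


def point_segment_distance(p, a, b):
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
    return np.hypot(*(a + t * ab - p))


def ray_cast_inside(p, poly_coords):
    """Oracle point-in-polygon by ray casting (independent of shapely)."""
    x, y = p
    inside = False
    pts = list(poly_coords)
    for (x1, y1), (x2, y2) in zip(pts[:-1], pts[1:]):
        if (y1 > y) != (y2 > y):
            xcross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xcross:
                inside = not inside
    return inside


def random_monotone_polyline(rng, n_vertices=20, width=600.0):
    xs = np.sort(rng.uniform(0, width, n_vertices))
    xs[0], xs[-1] = 0.0, width
    xs += np.arange(n_vertices) * 1e-6  # guard strict monotonicity
    ys = 200.0 + rng.normal(0, 40.0, n_vertices)
    return LineString(np.column_stack([xs, ys]))


class TestInterfaceDistance:
    def test_cell_on_polyline_is_zero(self):
        line = LineString([(0, 0), (10, 0)])
        cells = pd.DataFrame({"x_px": [5.0], "y_px": [0.0]}, index=["c"])
        out = geometry.signed_distance_to_interface(cells, line)
        assert out["d_interface_px"].iloc[0] == 0.0

    @pytest.mark.parametrize("y,expected", [(50.0, 50.0), (-50.0, -50.0)])
    def test_axis_aligned_halfplane(self, y, expected):
        line = LineString([(0, 0), (100, 0)])
        cells = pd.DataFrame({"x_px": [10.0], "y_px": [y]}, index=["c"])
        out = geometry.signed_distance_to_interface(cells, line, maternal_side="above")
        assert out["d_interface_px"].iloc[0] == pytest.approx(expected)
        assert out["compartment"].iloc[0] == ("maternal" if y > 0 else "fetal")

    def test_matches_brute_force_resampling_oracle(self):
        rng = np.random.default_rng(42)
        line = random_monotone_polyline(rng)
        cells = pd.DataFrame(
            {"x_px": rng.uniform(-20, 620, 300), "y_px": rng.uniform(0, 500, 300)},
            index=[f"c{i}" for i in range(300)],
        )
        out = geometry.signed_distance_to_interface(cells, line)
        oracle = brute_force_polyline_distance(
            cells[["x_px", "y_px"]].to_numpy(), np.asarray(line.coords)
        )
        assert np.all(np.abs(out["d_interface_px"].abs().to_numpy() - oracle) < 0.02)

    def test_degenerate_polyline_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            geometry.signed_distance_to_interface(
                pd.DataFrame({"x_px": [0.0], "y_px": [0.0]}),
                LineString([(1, 1), (1, 1)]),
            )

    def test_zero_length_segments_collapsed(self):
        line = LineString([(0, 0), (5, 0), (5, 0), (10, 0)])
        cells = pd.DataFrame({"x_px": [5.0], "y_px": [3.0]}, index=["c"])
        out = geometry.signed_distance_to_interface(cells, line)
        assert out["d_interface_px"].iloc[0] == pytest.approx(3.0)


class TestVesselDistance:
    def circle(self, cx=0.0, cy=0.0, r=100.0):
        return Point(cx, cy).buffer(r, quad_segs=256)

    @pytest.mark.parametrize(
        "x,expected", [(60.0, 40.0), (150.0, -50.0), (100.0, 0.0)]
    )
    def test_circle_arithmetic(self, x, expected):
        cells = pd.DataFrame({"x_px": [x], "y_px": [0.0]}, index=["c"])
        out = geometry.signed_distance_to_vessel(cells, {0: self.circle()})
        assert out["d_vessel_px"].iloc[0] == pytest.approx(expected, abs=1e-2)

    def test_tie_breaks_to_lowest_vessel_id(self):
        vessels = {2: self.circle(0, 0, 50), 1: self.circle(200, 0, 50)}
        cells = pd.DataFrame({"x_px": [100.0], "y_px": [0.0]}, index=["c"])
        out = geometry.signed_distance_to_vessel(cells, vessels)
        assert out["nearest_vessel_id"].iloc[0] == 1

    def test_matches_brute_force_polygon_oracle(self):
        rng = np.random.default_rng(3)
        polys = {}
        for vid in range(3):
            cx, cy = rng.uniform(100, 500, 2)
            ang = np.sort(rng.uniform(0, 2 * np.pi, 8))
            rad = rng.uniform(30, 70, 8)
            polys[vid] = Polygon(
                np.column_stack([cx + rad * np.cos(ang), cy + rad * np.sin(ang)])
            )
        cells = pd.DataFrame(
            {"x_px": rng.uniform(0, 600, 500), "y_px": rng.uniform(0, 600, 500)},
            index=[f"c{i}" for i in range(500)],
        )
        out = geometry.signed_distance_to_vessel(cells, polys)
        for cid, row in cells.iterrows():
            p = row.to_numpy(float)
            best = np.inf
            best_sign = 0.0
            for vid in sorted(polys):
                coords = np.asarray(polys[vid].exterior.coords)
                d = min(
                    point_segment_distance(p, a, b)
                    for a, b in zip(coords[:-1], coords[1:])
                )
                if d < best:
                    best = d
                    best_sign = 1.0 if ray_cast_inside(p, coords) else -1.0
            got = out.loc[cid, "d_vessel_px"]
            assert abs(abs(got) - best) < 1e-6
            assert np.sign(got) == best_sign


class TestIsometryEquivariance:
    def test_rigid_motion_preserves_distances(self, small_section):
        section, _ = small_section
        cells = section.cells.head(200)
        base = geometry.signed_distance_to_interface(
            cells, section.interface, section.maternal_side
        )
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = np.array([123.0, -456.0])

        def transform(xy):
            return xy @ R.T + shift

        moved_cells = cells.copy()
        moved_cells[["x_px", "y_px"]] = transform(cells[["x_px", "y_px"]].to_numpy())
        moved_line = LineString(transform(np.asarray(section.interface.coords)))
        # rotated polyline is no longer x-monotone; compare unsigned distances
        import shapely

        pts = shapely.points(
            moved_cells["x_px"].to_numpy(), moved_cells["y_px"].to_numpy()
        )
        moved_d = shapely.distance(pts, moved_line)
        assert np.all(np.abs(moved_d - base["d_interface_px"].abs().to_numpy()) < 1e-6)


class TestBinning:
    def test_manual_binning(self):
        d = pd.Series([10.0, 110.0, 150.0], index=list("abc"))
        labels = pd.Series(["T", "T", "T"], index=list("abc"))
        prof = geometry.bin_composition(d, labels, geometry.BinningConfig(bin_width=100))
        assert prof.n.to_dict() == {0.0: 1, 100.0: 2}

    def test_single_type_proportions_are_one(self, small_section):
        section, _ = small_section
        d = geometry.compute_distances(section)
        one = section.cells[section.cells.cell_type == "EVT"]
        prof = geometry.bin_composition(
            d.loc[one.index, "d_interface_px"], one["cell_type"]
        )
        assert np.allclose(prof.proportions.to_numpy(), 1.0)

    def test_conservation_and_sum_to_one(self, small_section):
        section, _ = small_section
        d = geometry.compute_distances(section)
        cfg = geometry.BinningConfig(bin_width=100, side="maternal")
        prof = geometry.bin_composition(
            d["d_interface_px"], section.cells["cell_type"], cfg
        )
        eligible = (d["d_interface_px"] >= 0).sum()
        assert prof.counts.to_numpy().sum() == eligible
        sums = prof.proportions.sum(axis=1).to_numpy()
        assert np.all(np.abs(sums - 1.0) < 1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        d = pd.Series(rng.uniform(-300, 800, 200), index=[f"c{i}" for i in range(200)])
        lab = pd.Series(rng.choice(["A", "B"], 200), index=d.index)
        p1 = geometry.bin_composition(d, lab)
        perm = rng.permutation(200)
        p2 = geometry.bin_composition(d.iloc[perm], lab.iloc[perm])
        pd.testing.assert_frame_equal(p1.counts, p2.counts)

    def test_empty_input_gives_empty_profile(self):
        prof = geometry.bin_composition(
            pd.Series(dtype=float), pd.Series(dtype=object)
        )
        assert prof.counts.empty and prof.n.empty


class TestTileAdjacency:
    def cells_at(self, coords):
        return pd.DataFrame(
            {"x_px": [c[0] for c in coords], "y_px": [c[1] for c in coords]},
            index=[f"c{i}" for i in range(len(coords))],
        )

    def test_same_tile_k0(self):
        cells = self.cells_at([(10, 10), (40, 40)])
        pairs = geometry.tile_adjacency(cells, tile_px=50, k_tiles=0)
        assert len(pairs) == 1

    def test_chebyshev_boundary(self):
        # tiles (0,0) vs (5,0) adjacent at k=5; (6,0) not
        cells = self.cells_at([(10, 10), (5 * 50 + 10, 10), (6 * 50 + 10, 10)])
        pairs = geometry.tile_adjacency(cells, tile_px=50, k_tiles=5)
        got = {tuple(sorted(p)) for p in pairs.to_numpy()}
        assert ("c0", "c1") in got and ("c0", "c2") not in got

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(7)
        cells = pd.DataFrame(
            {"x_px": rng.uniform(0, 500, 200), "y_px": rng.uniform(0, 500, 200)},
            index=[f"c{i:03d}" for i in range(200)],
        )
        pairs = geometry.tile_adjacency(cells, tile_px=50, k_tiles=5)
        got = {tuple(sorted(p)) for p in pairs.to_numpy()}
        tx = np.floor(cells["x_px"] / 50).astype(int).to_numpy()
        ty = np.floor(cells["y_px"] / 50).astype(int).to_numpy()
        expected = set()
        ids = cells.index.to_list()
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                cheb = max(abs(tx[i] - tx[j]), abs(ty[i] - ty[j]))
                if cheb <= 5:
                    expected.add(tuple(sorted((ids[i], ids[j]))))
        assert got == expected


class TestDepthMatch:
    def test_pool_equals_group(self):
        d = pd.Series(np.linspace(0, 900, 50), index=[f"g{i}" for i in range(50)])
        res = geometry.depth_match(d, d, bin_px=100, seed=0)
        assert sorted(res.matched_ids) == sorted(d.index)
        assert res.pvalue > 0.9

    def test_single_bin_group(self):
        g = pd.Series([10.0, 20.0, 30.0], index=list("abc"))
        pool = pd.Series([5.0, 15.0, 25.0, 150.0, 250.0], index=list("vwxyz"))
        res = geometry.depth_match(g, pool, bin_px=100, seed=0)
        assert set(res.matched_ids) <= {"v", "w", "x"}

    def test_uniform_pool_balances(self):
        # group on [0, 1000], pool on [0, 2000]: matched set confined to [0, 1000]
        ok = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            g = pd.Series(rng.uniform(0, 1000, 150), index=[f"g{i}" for i in range(150)])
            pool = pd.Series(
                rng.uniform(0, 2000, 600), index=[f"p{i}" for i in range(600)]
            )
            res = geometry.depth_match(g, pool, bin_px=100, seed=seed)
            assert pool[res.matched_ids].max() < 1000 + 100
            if res.pvalue > 0.05:
                ok += 1
        assert ok >= 95

    def test_empty_pool_errors(self):
        g = pd.Series([10.0], index=["a"])
        pool = pd.Series([5000.0], index=["p"])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                geometry.depth_match(g, pool, bin_px=100, seed=0)
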