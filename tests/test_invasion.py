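"""iScore pipeline: splitting, windows, LASSO oracles, scoring, validation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ortho_group

import mfispatial as mfi
from mfispatial import expr, geometry, invasion
from mfispatial.invasion import (
    InvasionModel, Windows, build_windows, fit_model, lasso_fit,
    score_cells, split_train_test,
)


class TestSplit:
    def test_even_split(self):
        ids = pd.Index([f"c{i}" for i in range(1000)])
        a, b = split_train_test(ids, ratio=0.5, seed=0)
        assert len(a) == 500 and len(b) == 500

    def test_partition_laws(self):
        ids = pd.Index([f"c{i}" for i in range(517)])
        a, b = split_train_test(ids, ratio=0.5, seed=3)
        assert len(a.intersection(b)) == 0
        assert set(a) | set(b) == set(ids)

    def test_determinism(self):
        ids = pd.Index([f"c{i}" for i in range(100)])
        a1, b1 = split_train_test(ids, seed=7)
        a2, b2 = split_train_test(ids, seed=7)
        assert list(a1) == list(a2) and list(b1) == list(b2)


class TestEligibility:
    def test_vessel_associated_excluded(self, tissue):
        section, distances = tissue["section"], tissue["distances"]
        elig = invasion.eligible_evts(section.cells, distances)
        cells = section.cells.loc[elig]
        assert (cells["cell_type"] == "EVT").all()
        assert not cells["subtype"].isin(["eEVT", "pEVT"]).any()
        assert (distances.loc[elig, "d_vessel_px"].abs() > 200).all()


class TestWindows:
    def make_X(self, n, genes=3, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(size=(n, genes)),
            index=[f"c{i:03d}" for i in range(n)],
            columns=[f"G{j}" for j in range(genes)],
        )

    def test_single_window_mean_depth(self):
        X = self.make_X(10)
        depths = pd.Series(np.arange(1.0, 11.0), index=X.index)
        w = build_windows(depths, X, k=10)
        assert len(w.X) == 1
        assert w.depth.iloc[0] == pytest.approx(5.5)

    def test_remainder_dropped(self):
        X = self.make_X(25)
        depths = pd.Series(np.arange(25.0), index=X.index)
        with pytest.warns(UserWarning, match="5 cells"):
            w = build_windows(depths, X, k=10)
        assert len(w.X) == 2 and w.n_dropped == 5

    def test_window_mean_is_arithmetic_mean(self):
        X = self.make_X(6, genes=3, seed=1)
        depths = pd.Series([5.0, 1.0, 3.0, 2.0, 6.0, 4.0], index=X.index)
        w = build_windows(depths, X, k=3)
        # manual oracle: cells sorted by depth; first window = depths {1,2,3}
        first = depths.sort_values().index[:3]
        assert np.allclose(w.X.iloc[0].to_numpy(), X.loc[first].mean().to_numpy())

    def test_k_below_two_rejected(self):
        X = self.make_X(5)
        with pytest.raises(ValueError):
            build_windows(pd.Series(np.arange(5.0), index=X.index), X, k=1)


class TestLassoOracles:
    def test_lambda_zero_equals_ols(self):
        """lam=0 reproduces the normal-equations OLS solution."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + rng.normal(0, 0.1, 50)
        beta, b0 = lasso_fit(X, y, lam=0.0)
        Xd = np.column_stack([np.ones(50), X])
        ols = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        assert np.allclose(beta, ols[1:], atol=1e-6)
        assert b0 == pytest.approx(ols[0], abs=1e-6)

    def test_single_feature_ols_slope(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(80, 1))
        y = 2.5 * x[:, 0] + rng.normal(0, 0.2, 80)
        beta, _ = lasso_fit(x, y, lam=0.0)
        xc = x[:, 0] - x[:, 0].mean()
        slope = (xc @ (y - y.mean())) / (xc @ xc)
        assert beta[0] == pytest.approx(slope, abs=1e-8)

    def test_orthonormal_design_soft_threshold(self):
        """On an orthonormal design, beta_g = soft(b_ols_g, lam) exactly."""
        rng = np.random.default_rng(2)
        Q = ortho_group.rvs(30, random_state=3)[:, :8]  # 30x8, Q^T Q = I
        b_true = np.array([3.0, -2.0, 1.5, 0.4, -0.2, 0.0, 0.0, 5.0])
        y = Q @ b_true + rng.normal(0, 0.05, 30)
        b_ols = Q.T @ y
        for lam in (0.1, 0.5, 1.0, 2.5):
            beta, _ = lasso_fit(Q, y, lam=lam, fit_intercept=False)
            soft = np.sign(b_ols) * np.maximum(np.abs(b_ols) - lam, 0.0)
            assert np.allclose(beta, soft, atol=1e-8)

    def test_sparsity_nonincreasing_in_lambda(self):
        """Along an increasing lam grid the selected set never grows."""
        rng = np.random.default_rng(3)
        Q = ortho_group.rvs(40, random_state=4)[:, :10]
        y = Q @ rng.normal(0, 2, 10) + rng.normal(0, 0.1, 40)
        nnz = []
        for lam in np.geomspace(0.01, 5.0, 20):
            beta, _ = lasso_fit(Q, y, lam=lam, fit_intercept=False)
            nnz.append(int(np.count_nonzero(beta)))
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_constant_response_all_zero(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(
            rng.normal(size=(40, 6)), columns=[f"G{j}" for j in range(6)],
            index=[f"w{i}" for i in range(40)],
        )
        w = Windows(
            X=X, depth=pd.Series(np.full(40, 7.0), index=X.index),
            members=[[i] for i in range(40)], n_dropped=0,
        )
        model = fit_model(w, seed=0)
        assert np.count_nonzero(model.beta) == 0


class TestScoring:
    def toy_model(self):
        return InvasionModel(
            features=["A", "B", "C"],
            mean=np.array([1.0, 2.0, 3.0]),
            sd=np.array([1.0, 2.0, 1.0]),
            lam=0.5,
            beta=np.array([2.0, 0.0, -1.0]),
            intercept=0.0,
            dropped_features=[], cv=None, path_nnz=[], seed=0,
        )

    def X_at_means(self, n=4):
        return pd.DataFrame(
            {"A": 1.0, "B": 2.0, "C": 3.0},
            index=[f"c{i}" for i in range(n)],
        )

    def test_cells_at_training_means_score_zero(self):
        out = score_cells(self.toy_model(), self.X_at_means())
        assert np.allclose(out["iscore_raw"], 0.0)

    def test_doubling_beta_doubles_raw_scores_only(self):
        rng = np.random.default_rng(5)
        X = self.X_at_means(20) + rng.normal(0, 1, (20, 3))
        m1 = self.toy_model()
        m2 = self.toy_model()
        m2.beta = 2.0 * m2.beta
        s1 = score_cells(m1, X)
        s2 = score_cells(m2, X)
        assert np.allclose(s2["iscore_raw"], 2.0 * s1["iscore_raw"])
        assert np.allclose(s2["iscore"], s1["iscore"], atol=1e-12)

    def test_identical_cells_identical_scores(self):
        X = self.X_at_means(2) + 1.0
        out = score_cells(self.toy_model(), X)
        assert out["iscore_raw"].iloc[0] == out["iscore_raw"].iloc[1]

    def test_section_normalization_moments(self):
        rng = np.random.default_rng(6)
        X = self.X_at_means(60) + rng.normal(0, 1, (60, 3))
        sections = pd.Series(
            ["s1"] * 30 + ["s2"] * 30, index=X.index
        )
        out = score_cells(self.toy_model(), X, sections=sections)
        for _, grp in out.groupby("section"):
            assert abs(grp["iscore"].mean()) < 1e-9
            assert abs(grp["iscore"].std(ddof=0) - 1.0) < 1e-9

    def test_too_many_missing_genes_rejected(self):
        # model with 3 selected genes; only 1 present (33% < the 50% floor)
        m = self.toy_model()
        m.beta = np.array([2.0, 1.0, -1.0])
        X = self.X_at_means()[["A"]]
        with pytest.raises(ValueError, match="50%"):
            score_cells(m, X)

    def test_half_coverage_allowed_with_warning(self):
        X = self.X_at_means()[["A"]]
        with pytest.warns(UserWarning, match="missing"):
            out = score_cells(self.toy_model(), X)
        assert np.allclose(out["iscore_raw"], 0.0)


class TestValidation:
    def test_overlap_with_training_rejected(self):
        m = TestScoring().toy_model()
        X = TestScoring().X_at_means(5)
        with pytest.raises(ValueError, match="overlap"):
            invasion.validate(m, X, pd.Series(1.0, index=X.index), train_ids=X.index[:1])

    def test_permuted_depths_null(self):
        rng = np.random.default_rng(7)
        n = 2000
        X = pd.DataFrame(
            rng.normal(size=(n, 3)), columns=["A", "B", "C"],
            index=[f"c{i}" for i in range(n)],
        )
        m = TestScoring().toy_model()
        depths = pd.Series(rng.permutation(np.linspace(0, 1000, n)), index=X.index)
        rep = invasion.validate(m, X, depths)
        assert abs(rep.rho) < 0.05


class TestLeakageGuard:
    def _fit_once(self, adata, section, distances, perturb_test: bool):
        depths = distances["d_interface_px"].abs()
        elig = invasion.eligible_evts(section.cells, distances)
        train, test = split_train_test(elig, 0.5, seed=42)
        if perturb_test:
            import scipy.sparse as sp

            X = adata.X.tolil()
            rows = adata.obs_names.get_indexer(test)
            X[rows, :] = 0  # destroy every held-out profile
            adata = adata.copy()
            adata.X = sp.csr_matrix(X)
        Xtr = expr.lognorm_df(adata, cells=train)
        w = build_windows(depths.loc[train], Xtr, k=10)
        model = fit_model(w, seed=42)
        return model.to_json()

    def test_model_bytes_invariant_to_test_perturbation(self):
        cfg = mfi.SectionConfig(
            n_evt=600, n_dsc=20, n_ec=0, n_immune=0, n_vct=0, n_sct=0,
            n_vessels=2, seed=13,
        )
        section, truth = mfi.generate_section(cfg)
        ecfg = mfi.ExpressionConfig(
            n_genes=300, n_invasion_genes=15, n_mimicry_genes=20, seed=13
        )
        adata, _ = mfi.generate_expression(section, ecfg, truth)
        distances = geometry.compute_distances(section)
        j1 = self._fit_once(adata, section, distances, perturb_test=False)
        j2 = self._fit_once(adata, section, distances, perturb_test=True)
        assert j1.encode() == j2.encode()


class TestBenchmarkExternal:
    def make_external(self, shift=0.0, n=300, seed=0):
        rng = np.random.default_rng(seed)
        genes = ["A", "B", "C"]
        lo = pd.DataFrame(
            rng.normal(0, 1, (n, 3)), columns=genes,
            index=[f"lo{i}" for i in range(n)],
        )
        hi = pd.DataFrame(
            rng.normal(0, 1, (n, 3)), columns=genes,
            index=[f"hi{i}" for i in range(n)],
        )
        lo[["A"]] -= shift  # A is pro-invasive in the toy model
        X = pd.concat([lo, hi])
        groups = pd.Series(["low"] * n + ["high"] * n, index=X.index)
        return X, groups

    def test_planted_low_invasion_group_detected(self):
        m = TestScoring().toy_model()
        X, groups = self.make_external(shift=0.5, seed=1)
        rep = invasion.benchmark_external(m, X, groups)
        assert rep.group_medians["low"] < rep.group_medians["high"]
        assert rep.pvalue < 0.01

    def test_label_swap_symmetry(self):
        m = TestScoring().toy_model()
        X, groups = self.make_external(shift=0.5, seed=2)
        p1 = invasion.benchmark_external(m, X, groups).pvalue
        swapped = groups.map({"low": "high", "high": "low"})
        p2 = invasion.benchmark_external(m, X, swapped).pvalue
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_null_p_uniformity(self):
        """Same-distribution groups: p-values are ~uniform (KS check)."""
        from scipy.stats import kstest

        m = TestScoring().toy_model()
        ps = []
        for seed in range(200):
            X, groups = self.make_external(shift=0.0, n=40, seed=seed)
            ps.append(invasion.benchmark_external(m, X, groups).pvalue)
        assert kstest(ps, "uniform").pvalue > 0.01
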