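"""Formulation sampling, ideal mixing, matching, process draw, solutions, SA."""

import numpy as np
import pandas as pd
import pytest

from fppid import design_engine as de
from fppid import latent, materials, synthetic
from fppid.materials import MODEL_FEATURES, PROCESS_COLUMNS, REDUCED_FEATURES


class TestSampleFormulations:
    def test_single_excipient_forced_composition(self):
        f = de.sample_formulations(s=1, m=0.3, b=10, seed=0)
        assert np.allclose(f.matrix, [[0.7, 0.3]] * 10)

    def test_constraints_hold_for_case_study_shape(self):
        f = de.sample_formulations(s=15, m=0.30, b=2000, max_excipients=5,
                                   seed=1)
        A = f.matrix
        assert A.shape == (2000, 16)
        # exhaustive row scan
        for i in range(2000):
            assert abs(A[i].sum() - 1.0) < 1e-10
            assert A[i, 0] == pytest.approx(0.70, abs=1e-10)
            assert 1 <= (A[i, 1:] > 0).sum() <= 5
            assert (A[i] >= 0).all()

    def test_seeded_reproducibility(self):
        a = de.sample_formulations(5, 0.4, 50, seed=9).matrix
        b = de.sample_formulations(5, 0.4, 50, seed=9).matrix
        assert np.array_equal(a, b)

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            de.sample_formulations(5, 1.2, 10)


class TestIdealMixing:
    def test_pure_drug_row_returns_drug_properties(self):
        I = np.arange(12.0).reshape(4, 3)
        A = np.array([[1.0, 0, 0, 0]])
        assert np.array_equal(de.ideal_mixing(A, I), I[:1])

    def test_fifty_fifty_is_arithmetic_mean(self):
        I = np.array([[1.0, 10.0], [3.0, 30.0], [5.0, 50.0]])
        A = np.array([[0.5, 0.5, 0.0]])
        assert np.allclose(de.ideal_mixing(A, I), [[2.0, 20.0]])

    def test_matches_double_loop_product(self):
        rng = np.random.default_rng(0)
        A = rng.dirichlet(np.ones(5), size=7)
        I = rng.uniform(0, 10, size=(5, 4))
        AI = de.ideal_mixing(A, I)
        brute = np.array([[sum(A[i, k] * I[k, j] for k in range(5))
                           for j in range(4)] for i in range(7)])
        assert np.abs(AI - brute).max() < 1e-12

    def test_convexity_bounds(self):
        rng = np.random.default_rng(1)
        A = rng.dirichlet(np.ones(6), size=50)
        I = rng.uniform(-5, 5, size=(6, 8))
        AI = de.ideal_mixing(A, I)
        assert np.all(AI <= I.max(axis=0) + 1e-12)
        assert np.all(AI >= I.min(axis=0) - 1e-12)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(materials.SchemaError):
            de.ideal_mixing(np.ones((3, 4)) / 4, np.ones((5, 2)))


class TestWettingAgentMatching:
    def test_library_powder_matches_itself(self, library30):
        matcher = de.WettingAgentMatcher(n_pcs=3).fit(library30)
        X = library30.feature_matrix(MODEL_FEATURES)
        res = matcher.match(X[3:4])
        assert res["nearest_material_id"].iloc[0] == library30.material_ids[3]
        assert res["nearest_distance"].iloc[0] < 1e-10
        lo, hi = library30.ls_range(library30.material_ids[3])
        assert res["ls_min"].iloc[0] == lo and res["ls_max"].iloc[0] == hi

    def test_agrees_with_nearest_centroid_oracle(self, library30):
        matcher = de.WettingAgentMatcher(n_pcs=3).fit(library30)
        rng = np.random.default_rng(2)
        X = library30.feature_matrix(MODEL_FEATURES)
        # random convex mixtures of library powders
        W = rng.dirichlet(np.ones(30), size=100)
        M = W @ X
        res = matcher.match(M)
        scores = matcher.pca_.transform(M)
        agents = library30.table["wetting_agent"].to_numpy()
        lib_scores = matcher.pca_.transform(X)
        for agent_class in ("water", "alcohol95"):
            assert (agents == agent_class).any()
        cw = lib_scores[agents == "water"].mean(axis=0)
        ca = lib_scores[agents == "alcohol95"].mean(axis=0)
        for i in range(100):
            dw = np.linalg.norm(scores[i] - cw)
            da = np.linalg.norm(scores[i] - ca)
            expected = "water" if dw <= da else "alcohol95"
            assert res["wetting_agent"].iloc[i] == expected

    def test_single_class_library_rejected(self, library30):
        t = library30.table.copy()
        t["wetting_agent"] = "water"
        lib = materials.MaterialLibrary(t)
        with pytest.raises(ValueError, match="alcohol95"):
            de.WettingAgentMatcher().fit(lib)


def _matches_frame(n, agent="water", lo=0.1, hi=0.8):
    return pd.DataFrame({
        "wetting_agent": [agent] * n,
        "ls_min": [lo] * n, "ls_max": [hi] * n,
    })


def _densities_frame(n):
    return pd.DataFrame({"Da": [0.5] * n, "Dc": [0.65] * n, "Dt": [1.5] * n})


class TestSampleProcess:
    def test_grid_membership_exhaustive(self):
        grids = de.ProcessGrids()
        R = de.sample_process(_matches_frame(500), _densities_frame(500),
                              grids, seed=3)
        assert R["feasible"].all()
        for _, row in R.iterrows():
            assert row["rpm"] in grids.rpm
            assert row["liquid_mL"] in grids.liquid_mL
            assert row["WT"] in grids.wt_s
            assert row["force_kN"] in grids.force_kN
            assert row["LS"] == pytest.approx(row["liquid_mL"] * 1.0 / 300.0)

    def test_single_level_grids_give_identical_rows(self):
        grids = de.ProcessGrids(rpm=(600,), liquid_mL=(120,), wt_s=(240,),
                                force_kN=(5,))
        R = de.sample_process(_matches_frame(10), _densities_frame(10),
                              grids, seed=4)
        assert (R.nunique() <= 1).all()

    def test_infeasible_ls_range_flagged(self):
        # matched range unreachable with any grid level
        R = de.sample_process(_matches_frame(5, lo=1.2, hi=1.4),
                              _densities_frame(5), de.ProcessGrids(), seed=5)
        assert (~R["feasible"]).all()
        assert R["LS"].isna().all()

    def test_derived_columns_consistent(self):
        from fppid import granulation
        R = de.sample_process(_matches_frame(50), _densities_frame(50),
                              de.ProcessGrids(), seed=6)
        for _, row in R.head(10).iterrows():
            assert row["Fr"] == pytest.approx(
                granulation.froude_number(row["rpm"]))
            assert row["Smax"] == pytest.approx(
                granulation.max_pore_saturation(row["LS"], 0.5, 1.0, 0.65, 1.5))


@pytest.fixture(scope="module")
def fitted_model(observations720):
    obs, _ = observations720
    feats = REDUCED_FEATURES + PROCESS_COLUMNS
    return latent.fit_pls(obs[feats].to_numpy(), obs[["TS", "SF"]].to_numpy(),
                          6, feature_names=feats, response_names=["TS", "SF"])


class TestGenerateSolutions:
    def _simulate(self, fitted_model, library30, n=200, seed=0):
        X = library30.feature_matrix(MODEL_FEATURES)
        rng = np.random.default_rng(seed)
        W = rng.dirichlet(np.ones(30), size=n)
        AI28 = pd.DataFrame(W @ X, columns=MODEL_FEATURES)
        matcher = de.WettingAgentMatcher().fit(library30)
        matches = matcher.match(AI28.to_numpy())
        R = de.sample_process(matches, AI28[["Da", "Dc", "Dt"]], seed=seed)
        return AI28[REDUCED_FEATURES], R

    def test_impossible_target_empty(self, fitted_model, library30):
        AI, R = self._simulate(fitted_model, library30)
        sol = de.generate_solutions(fitted_model, AI, R,
                                    de.DesignTargets(ts_min=1e6))
        assert len(sol) == 0

    def test_survivors_pass_independent_filter(self, fitted_model, library30):
        AI, R = self._simulate(fitted_model, library30)
        targets = de.DesignTargets(ts_min=2.0, sf_range=(0.705, 0.995))
        sol = de.generate_solutions(fitted_model, AI, R, targets)
        # independent re-implementation of the constraint filter
        names = fitted_model.feature_names_
        air = pd.concat([AI.reset_index(drop=True), R.reset_index(drop=True)],
                        axis=1)
        X = air[names].to_numpy(float)
        pred = fitted_model.predict(X)
        t2 = fitted_model.hotelling_t2(X=X)
        q = fitted_model.spe(X)
        t2_lim = latent.t2_limit(6, fitted_model.n_train_, 0.05)
        spe_lim = latent.spe_limit(fitted_model._x_residual_train_, 0.05)
        expected = set()
        for i in range(len(X)):
            if not R["feasible"].iloc[i]:
                continue
            if (pred[i, 0] >= 2.0 and 0.705 <= pred[i, 1] <= 0.995
                    and t2[i] < t2_lim and q[i] < spe_lim):
                expected.add(i)
        assert set(sol.surviving.tolist()) == expected

    def test_filtering_idempotent(self, fitted_model, library30):
        AI, R = self._simulate(fitted_model, library30)
        targets = de.DesignTargets(ts_min=2.0, sf_range=(0.705, 0.995))
        sol = de.generate_solutions(fitted_model, AI, R, targets)
        sol2 = de.generate_solutions(fitted_model,
                                     AI.loc[sol.surviving].reset_index(drop=True),
                                     R.loc[sol.surviving].reset_index(drop=True),
                                     targets)
        assert len(sol2) == len(sol)

    def test_feature_mismatch_raises(self, fitted_model, library30):
        AI, R = self._simulate(fitted_model, library30)
        with pytest.raises(materials.SchemaError):
            de.generate_solutions(fitted_model, AI.drop(columns=["Dt"]), R)


class TestSensitivityAnalysis:
    def _material_vector(self, library30):
        return library30.feature_matrix(REDUCED_FEATURES)[0]

    def _ranges(self):
        return {"LS": (0.1, 0.8), "WT": (180, 300), "Fr": (0.63, 2.54),
                "Smax": (0.05, 0.6), "P": (12.7, 140.0)}

    def test_pear_bounded_and_shaped(self, fitted_model, library30):
        rep = de.sensitivity_analysis(self._material_vector(library30),
                                      fitted_model, self._ranges(), n=500,
                                      seed=1)
        assert rep.pear.shape == (5, 2)
        assert (rep.pear.abs() <= 1).all().all()

    def test_degenerate_range_flagged_zero(self, fitted_model, library30):
        ranges = self._ranges()
        ranges["WT"] = (240.0, 240.0)
        rep = de.sensitivity_analysis(self._material_vector(library30),
                                      fitted_model, ranges, n=500, seed=2)
        assert "WT" in rep.zero_variance
        assert rep.pear.loc["WT"].eq(0).all()

    def test_null_parameter_has_negligible_pear(self, library30):
        # truth independent of WT, trained on unaliased uniform process
        # draws so the fitted WT effect is pure estimation noise
        rng = np.random.default_rng(31)
        n = 2000
        feats = library30.feature_matrix(REDUCED_FEATURES)[0]
        proc = np.column_stack([
            rng.uniform(0.1, 0.8, n), rng.uniform(180, 300, n),
            rng.uniform(0.6, 2.6, n), rng.uniform(0.05, 0.6, n),
            rng.uniform(12.7, 140.0, n)])
        X = np.column_stack([
            feats + 0.01 * rng.standard_normal((n, len(feats))), proc])
        y = -2.0 * proc[:, 0] + 0.02 * proc[:, 4] + 0.1 * rng.standard_normal(n)
        Y = np.column_stack([y, 0.3 * y])
        names = REDUCED_FEATURES + PROCESS_COLUMNS
        m = latent.fit_pls(X, Y, 3, feature_names=names,
                           response_names=["TS", "SF"])
        rep = de.sensitivity_analysis(feats, m, self._ranges(), n=1000, seed=3)
        assert abs(rep.pear.loc["WT", "TS"]) < 0.1

    def test_matches_closed_form_correlation(self, library30):
        """For a fitted plane y = b1*LS + b2*P (+const), PEAR(LS, TS) must
        equal b1*sigma_LS / sqrt(b1^2 sigma_LS^2 + b2^2 sigma_P^2)."""
        rng = np.random.default_rng(4)
        n = 4000
        feats = library30.feature_matrix(REDUCED_FEATURES)[0]
        # build a training table where TS depends linearly on LS and P only
        X = np.tile(feats, (n, 1))
        proc = np.column_stack([
            rng.uniform(0.1, 0.8, n), rng.uniform(180, 300, n),
            rng.uniform(0.6, 2.6, n), rng.uniform(0.05, 0.6, n),
            rng.uniform(12.7, 140.0, n)])
        Xfull = np.column_stack([X + 0.01 * rng.standard_normal(X.shape), proc])
        b1, b2 = -2.0, 0.02
        y = b1 * proc[:, 0] + b2 * proc[:, 4]
        Y = np.column_stack([y, 0.5 * y + 1.0])
        names = REDUCED_FEATURES + PROCESS_COLUMNS
        m = latent.fit_pls(Xfull, Y, 2, feature_names=names,
                           response_names=["TS", "SF"])
        ranges = self._ranges()
        rep = de.sensitivity_analysis(feats, m, ranges, n=2000, seed=5)
        s_ls = (ranges["LS"][1] - ranges["LS"][0]) / np.sqrt(12)
        s_p = (ranges["P"][1] - ranges["P"][0]) / np.sqrt(12)
        expected = b1 * s_ls / np.hypot(b1 * s_ls, b2 * s_p)
        assert rep.pear.loc["LS", "TS"] == pytest.approx(expected, abs=0.05)
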