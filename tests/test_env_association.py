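"""Standardization, elastic-net fitting, key-metabolite selection, clustering."""

from __future__ import annotations

import subprocess

import numpy as np
import pandas as pd
import pytest

from metapot import (
    MetaboliteGroup,
    build_design,
    cluster_variables,
    fit_elastic_net,
    select_key_metabolites,
    standardize_env,
)
from metapot.env_association import AssociationResult


class TestStandardize:
    def test_centering_and_scaling(self):
        env = pd.DataFrame({"v": [1.0, 2, 3, 4, 5, 6]}, index=list("abcdef"))
        out = standardize_env(env)
        assert abs(out["v"].mean()) < 1e-12
        assert abs(out["v"].std(ddof=0) - 1) < 1e-12

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        env = pd.DataFrame(
            rng.normal(size=(6, 17)),
            index=[f"S{i}" for i in range(6)],
            columns=[f"v{i}" for i in range(17)],
        )
        once = standardize_env(env)
        twice = standardize_env(once)
        pd.testing.assert_frame_equal(once, twice)
        assert (once.mean().abs() < 1e-12).all()

    def test_constant_variable_named(self):
        env = pd.DataFrame({"ok": [1.0, 2], "flat": [3.0, 3]}, index=["a", "b"])
        with pytest.raises(ValueError, match="flat"):
            standardize_env(env)

    def test_missing_values_rejected(self):
        env = pd.DataFrame({"v": [1.0, np.nan]}, index=["a", "b"])
        with pytest.raises(ValueError, match="missing"):
            standardize_env(env)


class TestBuildDesign:
    def test_simulation_design_rows(self, small_world, small_world_matrix):
        from metapot import collapse_groups, filter_gapfill_artifacts

        filtered, _ = filter_gapfill_artifacts(small_world_matrix)
        groups = collapse_groups(filtered)
        design = build_design(groups, filtered, small_world.env)
        assert len(design.X) == 60
        assert set(design.site_of_obs) == set(small_world.sites)
        # the all-ones core group cannot inform the regression
        assert len(design.zero_variance) >= 1

    def test_site_design_rows(self, small_world, small_world_matrix):
        from metapot import collapse_groups, filter_gapfill_artifacts

        filtered, _ = filter_gapfill_artifacts(small_world_matrix)
        groups = collapse_groups(filtered)
        design = build_design(groups, filtered, small_world.env, unit="site")
        assert len(design.X) == len(small_world.sites)

    def test_unmapped_site_rejected(self, small_world, small_world_matrix):
        from metapot import collapse_groups, filter_gapfill_artifacts

        filtered, _ = filter_gapfill_artifacts(small_world_matrix)
        groups = collapse_groups(filtered)
        env = small_world.env.drop(index=["S1"])
        with pytest.raises(ValueError, match="S1"):
            build_design(groups, filtered, env)


def _planted_design(rng, n_obs=200, n_sites=10, n_decoys=20, effect=2.0, noise=0.1):
    sites = pd.Series([f"S{i % n_sites}" for i in range(n_obs)])
    X = pd.DataFrame(
        rng.integers(0, 2, size=(n_obs, n_decoys + 1)).astype(float),
        columns=["g_true"] + [f"g_decoy{i}" for i in range(n_decoys)],
    )
    y = pd.Series(effect * X["g_true"] + rng.normal(0, noise, n_obs), name="v")
    return X, y, sites


class TestElasticNet:
    def test_planted_parameter_recovery(self):
        rng = np.random.default_rng(42)
        X, y, sites = _planted_design(rng)
        res = fit_elastic_net(X, y, sites, seed=0)
        assert abs(res.coefficients["g_true"]) > 0.5
        decoys = res.coefficients.drop("g_true")
        assert (decoys.abs() < 0.05).all()

    def test_null_model_mostly_empty(self):
        # y independent of all predictors: selected-penalty fit should be
        # all-zero in at least 95% of replicates
        rng = np.random.default_rng(9)
        empty = 0
        n_rep = 100
        for _ in range(n_rep):
            X = pd.DataFrame(
                rng.integers(0, 2, size=(60, 15)).astype(float),
                columns=[f"g{i}" for i in range(15)],
            )
            sites = pd.Series([f"S{i % 6}" for i in range(60)])
            y = pd.Series(rng.normal(size=60), name="v")
            res = fit_elastic_net(X, y, sites, seed=0)
            if (res.coefficients == 0).all():
                empty += 1
        assert empty >= 0.95 * n_rep

    def test_pure_lasso_matches_soft_threshold(self):
        # mixing 1, one standardized predictor: coef = sign(r) * max(|r|-lam, 0)
        rng = np.random.default_rng(3)
        n = 60
        sites = pd.Series([f"S{i % 6}" for i in range(n)])
        x = rng.normal(size=n)
        y_raw = 0.8 * x + rng.normal(0, 0.5, n)
        X = pd.DataFrame({"g": x})
        y = pd.Series(y_raw, name="v")
        res = fit_elastic_net(X, y, sites, mixing=1.0, seed=0)
        xs = (x - x.mean()) / x.std()
        ys = (y_raw - y_raw.mean()) / y_raw.std()
        r = float(xs @ ys) / n
        expected = np.sign(r) * max(abs(r) - res.penalty, 0.0)
        assert res.coefficients["g"] == pytest.approx(expected, abs=1e-6)

    def test_zero_variance_predictors_get_zero(self):
        rng = np.random.default_rng(4)
        X, y, sites = _planted_design(rng, n_decoys=5)
        X["g_const"] = 1.0
        res = fit_elastic_net(X, y, sites, zero_variance=["g_const"], seed=0)
        assert res.coefficients["g_const"] == 0.0

    def test_invariant_to_duplicating_fold_preserving_block(self):
        rng = np.random.default_rng(5)
        X, y, sites = _planted_design(rng, n_obs=60, n_sites=6, n_decoys=8)
        res1 = fit_elastic_net(X, y, sites, seed=0)
        X2 = pd.concat([X, X], ignore_index=True)
        y2 = pd.concat([y, y], ignore_index=True)
        sites2 = pd.concat([sites, sites], ignore_index=True)
        res2 = fit_elastic_net(X2, y2, sites2, seed=0)
        assert np.allclose(res1.coefficients, res2.coefficients, atol=1e-4)

    def test_single_site_rejected(self):
        rng = np.random.default_rng(6)
        X, y, _ = _planted_design(rng, n_obs=10)
        with pytest.raises(ValueError, match="2 sites"):
            fit_elastic_net(X, y, pd.Series(["S0"] * 10), seed=0)

    def test_matches_glmnet_at_same_penalty(self, tmp_path):
        # independent oracle: R glmnet at the penalty this fit selected
        rng = np.random.default_rng(7)
        X, y, sites = _planted_design(rng, n_obs=120, n_sites=6, n_decoys=6)
        res = fit_elastic_net(X, y, sites, seed=0)
        informative = [c for c in X.columns]
        Xs = (X - X.mean()) / X.std(ddof=0)
        ys = (y - y.mean()) / y.std(ddof=0)
        Xs.to_csv(tmp_path / "X.csv", index=False)
        ys.to_frame().to_csv(tmp_path / "y.csv", index=False)
        script = f"""
        suppressMessages(library(glmnet))
        X <- as.matrix(read.csv("{tmp_path}/X.csv"))
        y <- read.csv("{tmp_path}/y.csv")$v
        fit <- glmnet(X, y, alpha = 0.85, lambda = {res.penalty},
                      standardize = FALSE, intercept = TRUE)
        write.csv(as.matrix(coef(fit)), "{tmp_path}/coef.csv")
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        coefs = pd.read_csv(tmp_path / "coef.csv", index_col=0)["s0"]
        for col in informative:
            assert res.coefficients[col] == pytest.approx(coefs[col], abs=0.01)


def _results_from_coefs(coef_by_var: dict[str, dict[str, float]], group_ids):
    results = {}
    for var, coefs in coef_by_var.items():
        series = pd.Series(0.0, index=group_ids, name=var)
        for gid, c in coefs.items():
            series[gid] = c
        results[var] = AssociationResult(
            variable=var, coefficients=series, intercept=0.0, mixing=0.85,
            penalty=0.1, n_obs=60, unit="simulation", seed=0,
        )
    return results


class TestSelection:
    GROUPS = [
        MetaboliteGroup("g1", ("m1", "m2"), (1, 0)),
        MetaboliteGroup("g2", ("m3",), (0, 1)),
        MetaboliteGroup("g3", ("m4",), (1, 1)),
    ]

    def test_boundary_is_strict(self):
        results = _results_from_coefs(
            {"pH": {"g1": 0.3, "g2": -0.45}}, ["g1", "g2", "g3"]
        )
        keys = select_key_metabolites(results, self.GROUPS, 0.3)
        assert keys.selected_groups == ["g2"]
        assert keys.key_metabolites == {"m3"}

    def test_union_across_variables(self):
        results = _results_from_coefs(
            {"pH": {"g1": 0.5}, "EC": {"g3": -0.31}}, ["g1", "g2", "g3"]
        )
        keys = select_key_metabolites(results, self.GROUPS, 0.3)
        assert keys.selected_groups == ["g1", "g3"]
        assert keys.key_metabolites == {"m1", "m2", "m4"}

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(8)
        coefs = {f"v{i}": {"g1": rng.normal(), "g2": rng.normal()} for i in range(5)}
        results = _results_from_coefs(coefs, ["g1", "g2", "g3"])
        previous = None
        for thr in (0.0, 0.2, 0.4, 0.8, 1.5):
            selected = set(select_key_metabolites(results, self.GROUPS, thr).selected_groups)
            if previous is not None:
                assert selected <= previous
            previous = selected


class TestClusterVariables:
    def test_identical_profiles_merge_at_zero(self):
        coef = pd.DataFrame(
            {"a": [0.5, 0.2], "b": [0.5, 0.2], "c": [0.0, 0.9]},
            index=["g1", "g2"],
        )
        clustering = cluster_variables(coef, n_clusters=2)
        Z = clustering.linkage_matrix
        assert Z[0, 2] == pytest.approx(0.0)
        clusters = clustering.flat_clusters
        assert clusters["a"] == clusters["b"] != clusters["c"]

    def test_sign_ignored_in_profiles(self):
        coef = pd.DataFrame({"a": [0.5, -0.2], "b": [-0.5, 0.2]}, index=["g1", "g2"])
        clustering = cluster_variables(coef, n_clusters=2)
        assert clustering.linkage_matrix[0, 2] == pytest.approx(0.0)

    def test_linkage_heights_monotone(self):
        rng = np.random.default_rng(10)
        coef = pd.DataFrame(
            rng.uniform(0, 1, size=(12, 8)),
            index=[f"g{i}" for i in range(12)],
            columns=[f"v{i}" for i in range(8)],
        )
        heights = cluster_variables(coef, n_clusters=3).linkage_matrix[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_all_zero_profile_rejected(self):
        coef = pd.DataFrame({"a": [0.5, 0.1], "dead": [0.0, 0.0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="dead"):
            cluster_variables(coef)

    def test_needs_two_variables(self):
        coef = pd.DataFrame({"a": [0.5]}, index=["g1"])
        with pytest.raises(ValueError, match="2 variables"):
            cluster_variables(coef)
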