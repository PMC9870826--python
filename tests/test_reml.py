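import numpy as np
import pandas as pd
import pytest

from vcusim.reml import (
    DesignError,
    EstimabilityError,
    MODEL2_RANDOM,
    MODEL5_RANDOM,
    ModelSpec,
    blup_H,
    build_design,
    reml_fit,
    solve_mme,
)

from _oracle import dense_mme_blup, dense_reml, dense_restricted_ll
from conftest import random_crossed_dataset


class TestBuildDesign:
    def test_indicator_shapes_and_row_sums(self):
        df = pd.DataFrame(
            {"year": [1, 1, 2, 2], "y": [1.0, 2, 3, 4], "t": [1, 1, 2, 2], "r": [1, 2, 1, 2]}
        )
        d = build_design(df, ModelSpec(fixed=("t",), random=("year",)))
        Z = d.Z["year"].toarray()
        assert Z.shape == (4, 2)
        assert (Z.sum(axis=1) == 1).all()

    def test_interaction_columns_only_for_observed_combinations(self):
        df = pd.DataFrame(
            {
                "year": [1, 1, 2],
                "location": [1, 2, 1],
                "y": [1.0, 2, 3],
            }
        )
        d = build_design(df, ModelSpec(fixed=(), random=("year_location",)))
        assert d.Z["year_location"].shape[1] == 3  # (2,2) never observed

    def test_level_counts_match_distinct_levels(self, small_fixture):
        _, dataset = small_fixture
        spec = ModelSpec(fixed=("t", "r"), random=MODEL5_RANDOM)
        d = build_design(dataset.data, spec)
        for f, keys in (("year", ["year"]), ("genotype_year", ["genotype", "year"])):
            expect = dataset.data.drop_duplicates(keys).shape[0]
            assert d.Z[f].shape[1] == expect

    def test_unresolvable_key_raises(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "t": [1, 2], "r": [1, 1]})
        with pytest.raises(DesignError):
            build_design(df, ModelSpec(fixed=("t",), random=("block",)))

    def test_duplicate_factor_rejected(self):
        with pytest.raises(DesignError):
            ModelSpec(fixed=(), random=("year", "year"))

    def test_collinear_fixed_design_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2, 3], "t": [1, 2, 3], "r": [1, 2, 3]})
        with pytest.raises(EstimabilityError):
            build_design(df, ModelSpec(fixed=("t", "r"), random=()))


class TestBalancedOneWay:
    """3 groups x 4 replicates: REML equals closed-form ANOVA estimators."""

    y = np.array(
        [12.1, 11.8, 12.6, 12.3, 14.0, 13.6, 14.4, 13.9, 10.9, 11.3, 10.6, 11.0]
    )

    def frame(self):
        return pd.DataFrame(
            {
                "genotype": np.repeat(["a", "b", "c"], 4),
                "y": self.y,
                "t": 1,
                "r": 1,
            }
        )

    def test_matches_anova_closed_form(self):
        df = self.frame()
        gm = df.groupby("genotype")["y"].mean()
        msb = 4 * gm.var(ddof=1)
        msw = float(
            df.groupby("genotype")["y"].apply(lambda s: ((s - s.mean()) ** 2).sum()).sum()
            / (len(df) - 3)
        )
        fit = reml_fit(df, ModelSpec(fixed=(), random=("genotype",)), tol=1e-12)
        assert fit.vc["residual"] == pytest.approx(msw, rel=1e-6)
        assert fit.vc["genotype"] == pytest.approx(max(0.0, (msb - msw) / 4), rel=1e-6)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_dense_brute_force(self, seed):
        """On tiny random crossed instances the sparse AI-REML fit agrees
        with a dense brute-force restricted-likelihood maximizer: restricted
        log-likelihoods to 1e-6, variance components to 1e-4 wherever the
        likelihood has curvature (in numerically flat directions the argmax
        is not determined to that precision by double arithmetic, so there
        the two maximizers are compared in likelihood instead)."""
        rng = np.random.default_rng(100 + seed)
        df = random_crossed_dataset(rng)
        factors = ("year", "location", "genotype")
        spec = ModelSpec(fixed=("t", "r"), random=factors)
        fit = reml_fit(df, spec, tol=1e-12)
        d = build_design(df, spec)
        Zs = [d.Z[f].toarray() for f in factors]
        ll_oracle, theta_oracle = dense_reml(d.y, d.X, Zs, seed=seed)
        theta_fit = np.array([fit.vc[f] for f in factors] + [fit.vc["residual"]])
        ll_fit_dense = dense_restricted_ll(
            d.y, d.X, Zs, np.maximum(theta_fit[:-1], 1e-12), theta_fit[-1]
        )
        scale = 1 + abs(ll_oracle)
        assert ll_fit_dense >= ll_oracle - 1e-6 * scale
        assert abs(fit.loglik - ll_fit_dense) < 1e-6 * scale
        vc_tol = 1e-4 * (1 + np.var(d.y))
        if not np.allclose(theta_fit, theta_oracle, atol=vc_tol):
            # both are maximizers far beyond the ll criterion; the parameter
            # gap lies in a flat direction of the restricted likelihood
            assert abs(ll_fit_dense - ll_oracle) < 1e-9 * scale

    def test_blups_match_dense_henderson_solve(self, small_fixture):
        _, dataset = small_fixture
        spec = ModelSpec(fixed=("t", "r"), random=("year", "location", "genotype"))
        variances = {"year": 25.0, "location": 53.0, "genotype": 13.0}
        d = build_design(dataset.data, spec)
        beta, blups = solve_mme(d, variances, 20.0)
        Zs = [d.Z[f].toarray() for f in variances]
        beta_o, u_o = dense_mme_blup(
            d.y, d.X, Zs, [variances[f] for f in variances], 20.0
        )
        assert np.allclose(beta, beta_o, atol=1e-8)
        for f, u in zip(variances, u_o):
            assert np.allclose(blups[f].to_numpy(), u, atol=1e-8)


class TestFitProperties:
    def test_translation_changes_only_intercept(self):
        rng = np.random.default_rng(5)
        df = random_crossed_dataset(rng)
        spec = ModelSpec(fixed=("t", "r"), random=("year", "genotype"))
        f1 = reml_fit(df, spec, tol=1e-10)
        df2 = df.assign(y=df["y"] + 100.0)
        f2 = reml_fit(df2, spec, tol=1e-10)
        assert f2.fixed["intercept"] - f1.fixed["intercept"] == pytest.approx(100, abs=1e-5)
        assert f2.fixed["t"] == pytest.approx(f1.fixed["t"], abs=1e-6)
        assert f2.fixed["r"] == pytest.approx(f1.fixed["r"], abs=1e-6)
        for k in f1.vc:
            assert f2.vc[k] == pytest.approx(f1.vc[k], abs=1e-5)

    def test_full_shrinkage_zeroes_genotype_blups(self):
        rng = np.random.default_rng(11)
        df = random_crossed_dataset(rng)
        # response carries no genotype signal at all
        df["y"] = 10.0 + 0.1 * df["t"] + rng.normal(0, 1, len(df))
        d = build_design(df, ModelSpec(fixed=("t",), random=("year", "genotype")))
        _, blups = solve_mme(d, {"year": 1.0, "genotype": 1e-12}, 1.0)
        assert np.allclose(blups["genotype"].to_numpy(), 0.0, atol=1e-6)

    def test_blups_approach_truth_as_noise_vanishes(self, one_cycle_toy):
        from vcusim.simulate import VarianceComponents, draw_effects, assemble_dataset
        from vcusim.selection import run_selection

        vc = VarianceComponents(
            sigma2_Y=0, sigma2_L=0, sigma2_LY=0, sigma2_LYT=0,
            sigma2_GL=0, sigma2_GY=0, sigma2_GLY=0, sigma2_e=1e-6,
        )
        effects = draw_effects(one_cycle_toy, vc, seed=2)
        sel = run_selection(one_cycle_toy, vc, effects, seed=2)
        ds = assemble_dataset(one_cycle_toy, vc, 2, sel)
        spec = ModelSpec(fixed=(), random=("genotype",))
        d = build_design(ds.data, spec)
        _, blups = solve_mme(d, {"genotype": vc.sigma2_G}, 1e-6)
        truth = ds.truth_H()
        g = blups["genotype"]
        observed = g.index
        assert np.allclose(
            g.to_numpy() - g.mean(),
            truth.reindex(observed).to_numpy() - truth.reindex(observed).mean(),
            atol=1e-2,
        )

    def test_model2_collapses_without_duplicates(self):
        rng = np.random.default_rng(21)
        df = random_crossed_dataset(rng)
        df = df.drop_duplicates(["genotype", "year", "location"])
        spec = ModelSpec(fixed=("t",), random=("year", "genotype", "genotype_year_location"))
        resolved = spec.resolve(df)
        assert "genotype_year_location" not in resolved.random

    def test_dense_and_sparse_paths_agree(self, small_fixture):
        """Forcing the sparse LU path reproduces the dense Cholesky fit."""
        _, dataset = small_fixture
        spec = ModelSpec(fixed=("t", "r"), random=("year", "location", "genotype"))
        dense = reml_fit(dataset.data, spec, tol=1e-10)
        sparse = reml_fit(dataset.data, spec, tol=1e-10, dense_limit=0)
        assert sparse.loglik == pytest.approx(dense.loglik, abs=1e-7)
        for k in dense.vc:
            assert sparse.vc[k] == pytest.approx(dense.vc[k], abs=1e-6)
        assert sparse.fixed["r"] == pytest.approx(dense.fixed["r"], abs=1e-8)

    def test_blup_H_requires_genotype_factor(self):
        rng = np.random.default_rng(3)
        df = random_crossed_dataset(rng)
        fit = reml_fit(df, ModelSpec(fixed=("t",), random=("year",)), tol=1e-8)
        with pytest.raises(KeyError):
            blup_H(fit)
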