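import numpy as np
import pandas as pd
import pytest
from scipy.stats import linregress

from ecoregion_beta import (DistanceMatrix, alpha_regression, commonality,
                            mrm, resampling_robustness, run_beta_analysis,
                            variance_partition)
from ecoregion_beta.core_data import ValidationError

from conftest import random_distance_matrix, random_occurrence


class TestAlphaRegression:
    def test_perfect_fit(self):
        x = np.arange(10.0)
        res = alpha_regression(3 * x + 2, x)
        assert res.adj_r2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(3.0)

    def test_adjusted_r2_formula_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        res = alpha_regression(y, x)
        expect = 1 - (1 - res.r2) * (res.n - 1) / (res.n - 2)
        assert res.adj_r2 == pytest.approx(expect)
        assert res.adj_r2 <= res.r2

    def test_noise_predictor_can_go_negative(self):
        rng = np.random.default_rng(3)
        # pure-noise predictor: adjusted R2 must be allowed below zero
        res = alpha_regression(rng.normal(size=12), rng.normal(size=12))
        assert res.adj_r2 < res.r2
        assert res.p_value > 0.0

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValidationError):
            alpha_regression(np.arange(5.0), np.ones(5))


class TestMRM:
    def test_self_regression_is_perfect(self):
        rng = np.random.default_rng(1)
        labels = [f"e{i}" for i in range(8)]
        D = random_distance_matrix(rng, labels)
        res = mrm(D, [("self", D)], nperm=199, seed=0)
        assert res.coefficients["self"] == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)
        assert res.coef_p["self"] == pytest.approx(1 / 200)

    @pytest.mark.parametrize("seed", range(5))
    def test_single_predictor_matches_ols_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"e{i}" for i in range(8)]
        y_dm = random_distance_matrix(rng, labels)
        x_dm = random_distance_matrix(rng, labels)
        res = mrm(y_dm, [("x", x_dm)], nperm=99, seed=1)
        lr = linregress(x_dm.condensed(), y_dm.condensed())
        assert res.coefficients["x"] == pytest.approx(lr.slope)
        assert res.intercept == pytest.approx(lr.intercept)
        assert res.r2 == pytest.approx(lr.rvalue ** 2)

    def test_permutation_seed_reproducible(self):
        rng = np.random.default_rng(2)
        labels = [f"e{i}" for i in range(7)]
        y_dm = random_distance_matrix(rng, labels)
        x_dm = random_distance_matrix(rng, labels)
        a = mrm(y_dm, [("x", x_dm)], nperm=199, seed=5)
        b = mrm(y_dm, [("x", x_dm)], nperm=199, seed=5)
        assert a.coef_p == b.coef_p and a.r2_p == b.r2_p

    def test_label_alignment_is_automatic(self):
        rng = np.random.default_rng(3)
        labels = [f"e{i}" for i in range(6)]
        y_dm = random_distance_matrix(rng, labels)
        x_dm = random_distance_matrix(rng, labels)
        shuffled = x_dm.subset(labels[::-1])
        a = mrm(y_dm, [("x", x_dm)], nperm=99, seed=0)
        b = mrm(y_dm, [("x", shuffled)], nperm=99, seed=0)
        assert a.coefficients["x"] == pytest.approx(b.coefficients["x"])

    def test_exactly_collinear_predictors_rejected(self):
        rng = np.random.default_rng(4)
        labels = [f"e{i}" for i in range(6)]
        y_dm = random_distance_matrix(rng, labels)
        x_dm = random_distance_matrix(rng, labels)
        with pytest.raises(ValidationError, match="collinear"):
            mrm(y_dm, [("x1", x_dm), ("x2", x_dm)], nperm=99, seed=0)


class TestVariancePartition:
    def test_single_predictor_definitional(self):
        rng = np.random.default_rng(5)
        labels = [f"e{i}" for i in range(8)]
        y_dm = random_distance_matrix(rng, labels)
        x_dm = random_distance_matrix(rng, labels)
        part = variance_partition(y_dm, [("x", x_dm)])
        assert part.unique["x"] == pytest.approx(part.r2_full)
        assert part.joint == pytest.approx(0.0, abs=1e-12)
        assert part.components_sum() == pytest.approx(1.0)

    def test_near_duplicate_predictors_share_everything(self):
        # the duplicate carries a whiff of noise to stay this side of the
        # collinearity guard; its chance alignment with the response bounds
        # how close to zero the unique terms can get
        rng = np.random.default_rng(6)
        labels = [f"e{i}" for i in range(16)]
        y_dm = random_distance_matrix(rng, labels)
        x = random_distance_matrix(rng, labels)
        jitter = x.values + rng.normal(0, 1e-4, x.values.shape)
        jitter = np.abs((jitter + jitter.T) / 2)
        np.fill_diagonal(jitter, 0.0)
        x2 = DistanceMatrix(jitter, labels)
        part = variance_partition(y_dm, [("a", x), ("b", x2)])
        assert part.unique["a"] == pytest.approx(0.0, abs=0.05)
        assert part.unique["b"] == pytest.approx(0.0, abs=0.05)
        assert part.joint == pytest.approx(part.r2_full, abs=0.1)

    def test_orthogonal_predictors_have_no_joint_fraction(self):
        # construct two predictor vectors orthogonal after centering
        labels = [f"e{i}" for i in range(5)]  # 10 pairs
        base = np.full(10, 5.0)
        c1 = np.array([1, -1, 1, -1, 1, -1, 1, -1, 1, -1], dtype=float)
        c2 = np.array([1, 1, -1, -1, 1, 1, -1, -1, 1, 1], dtype=float)
        assert (c1 - c1.mean()) @ (c2 - c2.mean()) == pytest.approx(0.0)
        x1 = DistanceMatrix.from_condensed(base + c1, labels)
        x2 = DistanceMatrix.from_condensed(base + c2, labels)
        y = DistanceMatrix.from_condensed(base + 0.6 * c1 + 0.3 * c2, labels)
        part = variance_partition(y, [("x1", x1), ("x2", x2)])
        marg = commonality(y, [("x1", x1), ("x2", x2)])
        assert part.joint == pytest.approx(0.0, abs=1e-9)
        assert part.unique["x1"] == pytest.approx(marg[("x1",)], abs=1e-9)
        assert part.unique["x2"] == pytest.approx(marg[("x2",)], abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_components_conservation_on_random_problems(self, seed):
        rng = np.random.default_rng(40 + seed)
        labels = [f"e{i}" for i in range(8)]
        y_dm = random_distance_matrix(rng, labels)
        preds = [(f"x{k}", random_distance_matrix(rng, labels))
                 for k in range(3)]
        part = variance_partition(y_dm, preds)
        assert part.components_sum() == pytest.approx(1.0, abs=1e-9)
        assert 0.0 <= part.unexplained <= 1.0


class TestResampling:
    def test_seed_determinism(self):
        rng = np.random.default_rng(7)
        pool = random_occurrence(rng, n_taxa=60, n_eco=8)
        a = resampling_robustness(pool, k=30, n_iter=10, nperm=99, seed=3)
        b = resampling_robustness(pool, k=30, n_iter=10, nperm=99, seed=3)
        assert a == b

    def test_mean_fit_improves_with_resample_size(self):
        rng = np.random.default_rng(8)
        pool = random_occurrence(rng, n_taxa=400, n_eco=10, p=0.3)
        means = [resampling_robustness(pool, k=k, n_iter=25, nperm=99,
                                       seed=11).mean_adj_r2
                 for k in (25, 100, 400)]
        assert means[0] < means[1] < means[2]

    def test_degenerate_pool_rejected(self):
        # identical incidence for every taxon collapses the Sørensen matrix
        # to all zeros, leaving nothing to regress on
        inc = pd.DataFrame(True, index=[f"t{i}" for i in range(10)],
                           columns=["a", "b", "c", "d"])
        from ecoregion_beta import OccurrenceMatrix
        pool = OccurrenceMatrix(inc, pd.Series("nonendemic", index=inc.index))
        with pytest.raises(ValidationError):
            resampling_robustness(pool, k=5, n_iter=5, nperm=99, seed=0)


class TestRunBetaAnalysis:
    def test_lithology_is_optional_and_drops_a_predictor(self, default_sim,
                                                         default_env):
        landscape, occ, _ = default_sim
        with_lith = run_beta_analysis(
            occ, default_env, landscape.grid,
            lith=landscape.lith_surfaces.div(
                landscape.lith_surfaces.sum(axis=1), axis=0),
            max_k=2, nperm=99, seed=1)
        without = run_beta_analysis(occ, default_env, landscape.grid,
                                    max_k=2, nperm=99, seed=1)
        for element in with_lith:
            assert set(with_lith[element].mrm.coefficients) == {
                "climatic", "altitudinal", "geographic", "lithological"}
            assert set(without[element].mrm.coefficients) == {
                "climatic", "altitudinal", "geographic"}
            assert without[element].partition.components_sum() == \
                pytest.approx(1.0)
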