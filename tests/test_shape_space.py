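"""Shape PCA, allometry regression and independent contrasts."""

import numpy as np
import pytest

from phylanchor.landmark_io import read_newick_string
from phylanchor.shape_space import (
    allometry_with_pic,
    independent_contrasts,
    regress_shape_on_size,
    shape_pca,
    size_correct,
)
from phylanchor.synthetic import simulate_bm_traits, simulate_tree

from conftest import random_yule_tree


class TestShapePCA:
    def test_identical_specimens_zero_eigenvalues(self, rng):
        flat = np.tile(rng.normal(size=10), (5, 1))
        space = shape_pca(flat)
        np.testing.assert_allclose(space.eigenvalues, 0, atol=1e-18)

    def test_rank_bound(self, rng):
        flat = rng.normal(size=(3, 12))
        space = shape_pca(flat)
        nonzero = np.sum(space.eigenvalues > 1e-12)
        assert nonzero <= 2

    def test_scores_preserve_pairwise_distances(self, rng):
        """Full-rank scores are a rotation of the centred data, so all
        inter-specimen distances survive exactly."""
        flat = rng.normal(size=(8, 14))
        space = shape_pca(flat)
        centred = flat - flat.mean(axis=0)
        d_data = np.linalg.norm(centred[:, None] - centred[None, :], axis=-1)
        d_scores = np.linalg.norm(
            space.scores[:, None] - space.scores[None, :], axis=-1
        )
        np.testing.assert_allclose(d_scores, d_data, atol=1e-9)

    def test_score_covariance_diagonal_and_centred(self, rng):
        flat = rng.normal(size=(9, 10))
        space = shape_pca(flat)
        np.testing.assert_allclose(space.scores.mean(axis=0), 0, atol=1e-9)
        cov = np.cov(space.scores, rowvar=False)
        np.testing.assert_allclose(cov - np.diag(np.diag(cov)), 0, atol=1e-9)
        np.testing.assert_allclose(np.diag(cov), space.eigenvalues, rtol=1e-9)

    def test_percent_variance_sums_to_100(self, rng):
        space = shape_pca(rng.normal(size=(7, 16)))
        assert space.percent_variance.sum() == pytest.approx(100.0)

    def test_too_few_specimens(self, rng):
        with pytest.raises(ValueError):
            shape_pca(rng.normal(size=(2, 8)))


class TestAllometryRegression:
    def test_fully_allometric_data(self, rng):
        z = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        direction = rng.normal(size=8)
        shapes = np.outer(z, direction) + rng.normal(size=8)  # constant offset
        fit = regress_shape_on_size(shapes, z, n_permutations=99, seed=0)
        assert fit.percent_predicted == pytest.approx(100.0, abs=1e-9)
        centred = fit.residual_shapes - fit.residual_shapes.mean(axis=0)
        np.testing.assert_allclose(centred, 0, atol=1e-9)

    def test_1d_toy(self):
        shapes = np.array([[1.0], [2.0], [3.0]])
        fit = regress_shape_on_size(shapes, np.array([1.0, 2.0, 3.0]), n_permutations=99, seed=0)
        assert fit.percent_predicted == pytest.approx(100.0)

    def test_shift_invariance_when_centered(self, rng):
        shapes = rng.normal(size=(8, 6))
        z = rng.normal(size=8)
        f1 = regress_shape_on_size(shapes, z, n_permutations=99, seed=1)
        f2 = regress_shape_on_size(shapes, z + 100.0, n_permutations=99, seed=1)
        assert f1.percent_predicted == pytest.approx(f2.percent_predicted, rel=1e-9)

    def test_null_p_values_roughly_uniform(self, rng):
        """Shapes independent of size: p should be non-degenerate and the
        average predicted share should match the 1/(n-1) null expectation
        of a random single-direction projection."""
        n = 12
        ps, pcts = [], []
        for i in range(100):
            shapes = rng.normal(size=(n, 10))
            z = rng.normal(size=n)
            fit = regress_shape_on_size(shapes, z, n_permutations=99, seed=int(rng.integers(2**31)))
            ps.append(fit.p_value)
            pcts.append(fit.percent_predicted)
        assert np.mean(pcts) == pytest.approx(100.0 / (n - 1), rel=0.25)
        ps = np.asarray(ps)
        assert 0.25 < np.mean(ps) < 0.75
        assert (ps <= 0.10).mean() < 0.25

    def test_constant_predictor_rejected(self, rng):
        with pytest.raises(ValueError, match="zero variance"):
            regress_shape_on_size(rng.normal(size=(5, 4)), np.ones(5))

    def test_residuals_orthogonal_to_predictor(self, rng):
        shapes = rng.normal(size=(9, 6))
        z = rng.normal(size=9)
        fit = regress_shape_on_size(shapes, z, n_permutations=99, seed=0)
        refit = regress_shape_on_size(fit.residual_shapes, z, n_permutations=99, seed=0)
        assert refit.percent_predicted < 1e-9


class TestIndependentContrasts:
    def test_two_taxon_closed_form(self):
        tree = read_newick_string("(A:1,B:1);")
        contrasts = independent_contrasts(tree, np.array([[0.0], [2.0]]), tip_labels=["A", "B"])
        assert contrasts.shape == (1, 1)
        assert abs(contrasts[0, 0]) == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_identical_values_give_zero_contrasts(self, rng):
        tree = random_yule_tree(rng, 8)
        traits = np.full((8, 3), 2.5)
        contrasts = independent_contrasts(tree, traits)
        np.testing.assert_allclose(contrasts, 0, atol=1e-12)

    def test_pic_slope_equals_gls_slope(self, rng):
        """The through-origin regression on contrasts reproduces the GLS
        slope under the Brownian covariance — an independent route."""
        from phylanchor.phylo_signal import phylo_covariance

        for trial in range(5):
            tree = random_yule_tree(rng, 6)
            labels = tree.as_arrays().tip_labels
            x = rng.normal(size=6)
            y = rng.normal(size=(6, 3))
            cx = independent_contrasts(tree, x.reshape(-1, 1), tip_labels=labels)[:, 0]
            cy = independent_contrasts(tree, y, tip_labels=labels)
            beta_pic = (cx @ cy) / (cx @ cx)
            c = phylo_covariance(tree).loc[labels, labels].to_numpy()
            cinv = np.linalg.inv(c)
            design = np.column_stack([np.ones(6), x])
            beta_gls = np.linalg.solve(design.T @ cinv @ design, design.T @ cinv @ y)
            np.testing.assert_allclose(beta_pic, beta_gls[1], atol=1e-8)

    def test_bm_contrasts_standardized(self, rng):
        """Contrasts of Brownian data are ~N(0, rate): mean within 3 SE,
        variance within 3 SE of the rate."""
        tree = simulate_tree(16, mode="yule", seed=99)
        rate = 2.0
        all_contrasts = []
        for i in range(100):
            traits = simulate_bm_traits(tree, p=1, rate=rate, seed=1000 + i)
            all_contrasts.append(independent_contrasts(tree, traits)[:, 0])
        c = np.concatenate(all_contrasts)
        se_mean = np.sqrt(rate / len(c))
        assert abs(c.mean()) < 3 * se_mean
        se_var = rate * np.sqrt(2.0 / len(c))
        assert abs(c.var() - rate) < 3 * se_var

    def test_label_mismatch(self, rng):
        tree = read_newick_string("(A:1,B:1);")
        with pytest.raises(ValueError, match="mismatch"):
            independent_contrasts(tree, np.zeros((2, 1)), tip_labels=["A", "X"])


class TestPicAllometry:
    def test_recovers_allometric_direction(self, rng):
        """shape = beta * logCS + BM noise at 4:1 signal-to-noise: the
        fitted vector points along beta (cosine > 0.9)."""
        tree = simulate_tree(12, mode="yule", seed=5)
        labels = tree.as_arrays().tip_labels
        beta = rng.normal(size=10)
        beta /= np.linalg.norm(beta)
        hits = 0
        for i in range(20):
            log_cs = simulate_bm_traits(tree, p=1, rate=1.0, seed=200 + i)[:, 0]
            noise = simulate_bm_traits(tree, p=10, rate=1.0 / 16.0, seed=300 + i)
            shapes = np.outer(log_cs, beta) + noise
            fit = allometry_with_pic(
                tree, shapes, log_cs, tip_labels=labels, n_permutations=99, seed=i
            )
            cos = abs(fit.coefficient_vector @ beta) / np.linalg.norm(fit.coefficient_vector)
            hits += cos > 0.9
        assert hits >= 18

    def test_no_allometry_under_pure_bm(self, rng):
        """Pure Brownian shape and size: p-values behave like a null."""
        tree = simulate_tree(10, mode="yule", seed=11)
        labels = tree.as_arrays().tip_labels
        ps = []
        for i in range(50):
            log_cs = simulate_bm_traits(tree, p=1, rate=1.0, seed=400 + i)[:, 0]
            shapes = simulate_bm_traits(tree, p=8, rate=1.0, seed=500 + i)
            fit = allometry_with_pic(
                tree, shapes, log_cs, tip_labels=labels, n_permutations=99, seed=i
            )
            ps.append(fit.p_value)
        ps = np.asarray(ps)
        assert 0.3 < ps.mean() < 0.7
        assert (ps <= 0.05).mean() <= 0.12

    def test_two_taxon_degenerate(self):
        tree = read_newick_string("(A:1,B:1);")
        shapes = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="degenerate"):
            fit = allometry_with_pic(
                tree, shapes, np.array([0.0, 1.0]), tip_labels=["A", "B"],
                n_permutations=99, seed=0,
            )
        assert fit.percent_predicted == pytest.approx(100.0)


class TestSizeCorrect:
    def test_zero_coefficient_identity(self, rng):
        shapes = rng.normal(size=(6, 8))
        z = rng.normal(size=6)
        # orthogonalize shapes to z so the slope is ~0
        zc = z - z.mean()
        shapes = shapes - np.outer(zc, (zc @ (shapes - shapes.mean(0))) / (zc @ zc))
        fit = regress_shape_on_size(shapes, z, n_permutations=99, seed=0)
        np.testing.assert_allclose(fit.coefficient_vector, 0, atol=1e-12)
        out = size_correct(shapes, fit)
        np.testing.assert_allclose(out, shapes, atol=1e-9)

    def test_corrected_shapes_size_free(self, rng):
        shapes = rng.normal(size=(8, 10))
        z = rng.normal(size=8)
        fit = regress_shape_on_size(shapes, z, n_permutations=99, seed=0)
        out = size_correct(shapes, fit)
        refit = regress_shape_on_size(out, z, n_permutations=99, seed=0)
        assert refit.percent_predicted < 1e-9

    def test_corrected_pca_matches_noise_component(self, rng):
        """With shape = allometric part + noise, the size-corrected PCA
        spectrum matches the PCA of the noise alone (within 5%)."""
        n, p = 20, 12
        z = rng.normal(size=n)
        direction = rng.normal(size=p)
        noise = rng.normal(scale=0.3, size=(n, p))
        zc = z - z.mean()
        # make the noise exactly orthogonal to the predictor
        noise = noise - np.outer(zc, (zc @ noise) / (zc @ zc))
        shapes = np.outer(z, direction) + noise
        fit = regress_shape_on_size(shapes, z, n_permutations=99, seed=0)
        out = size_correct(shapes, fit)
        eig_corr = shape_pca(out).eigenvalues
        eig_noise = shape_pca(noise).eigenvalues
        np.testing.assert_allclose(eig_corr, eig_noise, rtol=0.05, atol=1e-12)

    def test_dimension_mismatch(self, rng):
        shapes = rng.normal(size=(6, 8))
        fit = regress_shape_on_size(shapes, rng.normal(size=6), n_permutations=99, seed=0)
        with pytest.raises(ValueError):
            size_correct(rng.normal(size=(6, 10)), fit)
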