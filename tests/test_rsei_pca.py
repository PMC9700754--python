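import numpy as np
import pytest

from rseikit.raster_core import Grid
from rseikit.rsei_pca import (
    IndicatorStack,
    bartlett_sphericity,
    composite_index,
    kmo_statistic,
    principal_components,
    rsei_from_pc1,
    standardize,
)

from conftest import make_grid


def stack_from_arrays(ndvi, wet, lst, ndbsi) -> IndicatorStack:
    return IndicatorStack(ndvi=make_grid(ndvi), wet=make_grid(wet),
                          lst=make_grid(lst), ndbsi=make_grid(ndbsi))


def correlated_stack(rng, n_side=40, noise=0.05, loadings=(1.0, 0.7, -0.9, -0.8)):
    """Four indicators linear in one latent field plus iid noise."""
    latent = rng.normal(size=(n_side, n_side))
    arrays = [a * latent + rng.normal(0, noise, latent.shape) for a in loadings]
    return stack_from_arrays(*arrays), latent


class TestStandardize:
    def test_three_values(self):
        base = np.array([[1.0, 2.0, 3.0]])
        stack = stack_from_arrays(base, base * 2, base + 5, -base)
        out, record = standardize(stack)
        np.testing.assert_allclose(out.ndvi.values, [[-1.0, 0.0, 1.0]])
        assert record["ndvi"] == (2.0, 1.0)

    def test_idempotent_on_standardized_data(self, rng):
        stack, _ = correlated_stack(rng)
        once, _ = standardize(stack)
        twice, _ = standardize(once)
        np.testing.assert_allclose(twice.wet.values, once.wet.values, atol=1e-12)

    def test_zero_mean_unit_sd(self, rng):
        stack, _ = correlated_stack(rng)
        out, _ = standardize(stack)
        for g in out:
            vals = g.valid_values()
            assert abs(vals.mean()) < 1e-10
            assert abs(vals.std(ddof=1) - 1) < 1e-10

    def test_constant_indicator_named_in_error(self, rng):
        stack, _ = correlated_stack(rng)
        flat = stack.ndvi.with_values(np.full(stack.ndvi.shape, 0.7))
        bad = IndicatorStack(ndvi=flat, wet=stack.wet, lst=stack.lst, ndbsi=stack.ndbsi)
        with pytest.raises(ValueError, match="ndvi"):
            standardize(bad)


class TestDiagnostics:
    def test_kmo_equicorrelated(self):
        r = np.full((3, 3), 0.5)
        np.fill_diagonal(r, 1.0)
        # partial correlations rho/(1+rho) = 1/3; 0.75 / (0.75 + 1/3)
        assert kmo_statistic(r) == pytest.approx(0.75 / (0.75 + 1.0 / 3.0), abs=1e-12)

    def test_kmo_singular_matrix_rejected(self):
        r = np.ones((3, 3))
        with pytest.raises(ValueError):
            kmo_statistic(r)

    def test_bartlett_identity(self):
        stat, p = bartlett_sphericity(np.eye(4), 100)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_bartlett_equicorrelated_hand_value(self):
        r = np.full((3, 3), 0.5)
        np.fill_diagonal(r, 1.0)
        stat, p = bartlett_sphericity(r, 100)
        # det = (1-rho)^2 (1+2rho) = 0.5
        assert stat == pytest.approx(-(99 - 11 / 6) * np.log(0.5), rel=1e-12)
        assert p < 1e-6

    def test_bartlett_statistic_increases_with_n(self):
        r = np.full((3, 3), 0.3)
        np.fill_diagonal(r, 1.0)
        stats_ = [bartlett_sphericity(r, n)[0] for n in (50, 100, 200)]
        assert stats_[0] < stats_[1] < stats_[2]


class TestPrincipalComponents:
    def test_eigenvalues_sum_to_p(self, rng):
        stack, _ = correlated_stack(rng)
        std, _ = standardize(stack)
        pca = principal_components(std)
        assert pca.eigenvalues.sum() == pytest.approx(4.0)
        assert np.all(np.diff(pca.eigenvalues) <= 1e-12)

    def test_contribution_rates_sum_to_one(self, rng):
        stack, _ = correlated_stack(rng)
        std, _ = standardize(stack)
        pca = principal_components(std)
        assert pca.contribution_rates.sum() == pytest.approx(1.0)

    def test_eigenvectors_orthonormal(self, rng):
        stack, _ = correlated_stack(rng)
        std, _ = standardize(stack)
        pca = principal_components(std)
        np.testing.assert_allclose(pca.eigenvectors.T @ pca.eigenvectors,
                                   np.eye(4), atol=1e-10)

    def test_correlation_equals_covariance_pca_on_standardized_data(self, rng):
        stack, _ = correlated_stack(rng)
        std, _ = standardize(stack)
        pca = principal_components(std)
        data, _ = std.as_matrix()
        cov_eigvals = np.sort(np.linalg.eigvalsh(np.cov(data, rowvar=False)))[::-1]
        np.testing.assert_allclose(pca.eigenvalues, cov_eigvals, atol=1e-10)

    def test_pc1_tracks_latent_and_dominates(self, rng):
        stack, latent = correlated_stack(rng, noise=0.05)
        std, _ = standardize(stack)
        pca = principal_components(std)
        data, mask = std.as_matrix()
        scores = data @ pca.eigenvectors[:, 0]
        r = np.corrcoef(scores, latent[mask])[0, 1]
        assert abs(r) > 0.99
        assert pca.contribution_rates[0] > 0.6

    def test_pc1_sign_pattern_matches_loading_signs(self, rng):
        stack, _ = correlated_stack(rng, loadings=(1.0, 0.7, -0.9, -0.8))
        std, _ = standardize(stack)
        pca = principal_components(std)
        vec = pca.eigenvectors[:, 0]
        vec = vec if vec[0] > 0 else -vec
        assert vec[0] > 0 and vec[1] > 0 and vec[2] < 0 and vec[3] < 0


class TestRsei:
    def test_minmax_contract(self, rng):
        stack, _ = correlated_stack(rng)
        std, _ = standardize(stack)
        rsei = rsei_from_pc1(principal_components(std), std)
        vals = rsei.valid_values()
        assert vals.min() == pytest.approx(0.0, abs=1e-12)
        assert vals.max() == pytest.approx(1.0, abs=1e-12)

    def test_sign_orientation_invariant_to_negating_all_indicators(self, rng):
        stack, _ = correlated_stack(rng)
        std, _ = standardize(stack)
        r1 = rsei_from_pc1(principal_components(std), std)
        negated = IndicatorStack(**{
            name: getattr(stack, name).with_values(-getattr(stack, name).values)
            for name in ("ndvi", "wet", "lst", "ndbsi")
        })
        std2, _ = standardize(negated)
        r2 = rsei_from_pc1(principal_components(std2), std2)
        np.testing.assert_allclose(r1.values, 1.0 - r2.values, atol=1e-9)

    def test_rsei_monotone_in_latent(self, rng):
        from scipy.stats import spearmanr

        stack, latent = correlated_stack(rng, noise=0.05)
        std, _ = standardize(stack)
        rsei = rsei_from_pc1(principal_components(std), std)
        mask = rsei.valid_mask
        rho = spearmanr(rsei.values[mask], latent[mask]).statistic
        assert rho > 0.99

    def test_invariant_to_affine_transform_of_one_indicator(self, rng):
        stack, _ = correlated_stack(rng)
        std, _ = standardize(stack)
        r1 = rsei_from_pc1(principal_components(std), std)
        shifted = IndicatorStack(
            ndvi=stack.ndvi.with_values(3.0 * stack.ndvi.values + 10.0),
            wet=stack.wet, lst=stack.lst, ndbsi=stack.ndbsi)
        std2, _ = standardize(shifted)
        r2 = rsei_from_pc1(principal_components(std2), std2)
        np.testing.assert_allclose(r1.values, r2.values, atol=1e-9)


class TestCompositeIndex:
    def test_m1_ranks_like_rsei(self, rng):
        from scipy.stats import spearmanr

        stack, _ = correlated_stack(rng)
        std, _ = standardize(stack)
        pca = principal_components(std)
        y = composite_index(pca, std, m=1)
        rsei = rsei_from_pc1(pca, std)
        mask = rsei.valid_mask
        rho = spearmanr(y.values[mask], rsei.values[mask]).statistic
        assert rho == pytest.approx(1.0)

    def test_weights_sum_to_one_any_m(self, rng):
        stack, _ = correlated_stack(rng)
        std, _ = standardize(stack)
        pca = principal_components(std)
        for m in (1, 2, 3, 4):
            w = pca.eigenvalues[:m] / pca.eigenvalues[:m].sum()
            assert w.sum() == pytest.approx(1.0)
            composite_index(pca, std, m=m)  # smoke: runs for every m

    def test_m_out_of_range(self, rng):
        stack, _ = correlated_stack(rng)
        std, _ = standardize(stack)
        pca = principal_components(std)
        with pytest.raises(ValueError):
            composite_index(pca, std, m=5)


def test_two_perfectly_correlated_variables_one_component():
    """p=2 harness: a duplicated variable puts all variance on PC1."""
    rng = np.random.default_rng(0)
    x = rng.normal(size=200)
    corr = np.corrcoef(np.column_stack([x, 2 * x + 1]), rowvar=False)
    eigvals = np.sort(np.linalg.eigvalsh(corr))[::-1]
    assert eigvals[0] / eigvals.sum() == pytest.approx(1.0)
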