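"""HLP solver: noise estimation, limits, monotone descent and an optimizer oracle."""

import numpy as np
import pytest
from scipy.optimize import minimize

from ramanmix import (
    HLPConfig,
    HybridLSPCA,
    PCAModel,
    SpectralLibrary,
    Spectrum,
    build_design,
    cls_fit,
    estimate_sigma,
    hlp_fit,
    weight_to_concentration,
)


def make_model(axis, mean, components, eigenvalues, n_samples=30):
    components = np.asarray(components, float).reshape(-1, axis.size)
    return PCAModel(
        axis=axis,
        mean=np.asarray(mean, float),
        components=components,
        eigenvalues=np.asarray(eigenvalues, float),
        n_samples=n_samples,
    )


class TestEstimateSigma:
    def test_identical_replicates_give_zero(self, axis):
        lib = SpectralLibrary(axis, np.tile(np.sin(axis / 50), (4, 1)))
        assert estimate_sigma(lib) == 0.0

    def test_constant_offset_pair(self, axis):
        # two replicates differing by +delta everywhere: var = delta^2/2
        delta = 0.3
        base = np.cos(axis / 100)
        lib = SpectralLibrary(axis, np.vstack([base, base + delta]))
        assert estimate_sigma(lib) == pytest.approx(delta / np.sqrt(2), rel=1e-12)

    def test_recovers_known_noise_level(self):
        sigma0 = 0.07
        rng = np.random.default_rng(5)
        axis = np.linspace(400, 1800, 700)
        lib = SpectralLibrary(axis, 1.0 + rng.normal(0, sigma0, size=(200, 700)))
        assert estimate_sigma(lib) == pytest.approx(sigma0, rel=0.05)

    def test_single_replicate_raises(self, axis):
        with pytest.raises(ValueError, match="2 replicate"):
            estimate_sigma(SpectralLibrary(axis, np.ones((1, axis.size))))


class TestWeightToConcentration:
    @pytest.mark.parametrize(
        "weight,ref,expected", [(1.0, 0.8, 0.8), (2**-3, 0.8, 0.1), (0.0, 0.8, 0.0)]
    )
    def test_scaling(self, weight, ref, expected):
        assert weight_to_concentration(weight, ref) == pytest.approx(expected)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            weight_to_concentration(1.0, 0.0)


@pytest.fixture
def mean_pair(axis, rng):
    m1 = np.exp(-0.5 * ((axis - 700) / 20) ** 2) + 0.3 * np.exp(-0.5 * ((axis - 1500) / 15) ** 2)
    m2 = np.exp(-0.5 * ((axis - 1100) / 120) ** 2) + 0.2
    return m1, m2


class TestCollapseLimits:
    def test_zero_variance_models_reduce_to_cls_on_means(self, axis, mean_pair, rng):
        m1, m2 = mean_pair
        models = [
            make_model(axis, m1, np.empty((0, axis.size)), []),
            make_model(axis, m2, np.empty((0, axis.size)), []),
        ]
        measured = Spectrum(axis, rng.normal(size=axis.size) + m1 + m2)
        res = hlp_fit(measured, models, HLPConfig(sigma=0.01))
        refs = [Spectrum(axis, m1), Spectrum(axis, m2)]
        expected = cls_fit(measured, build_design(refs, poly_order=-1)).weights
        np.testing.assert_allclose(res.weights, expected, atol=1e-10)

    def test_large_beta_pins_coefficients(self, axis, mean_pair, rng, orthonormal_rows):
        m1, m2 = mean_pair
        models = [
            make_model(axis, m1, orthonormal_rows(rng, 2, axis.size), [0.5, 0.1]),
            make_model(axis, m2, orthonormal_rows(rng, 2, axis.size), [0.4, 0.2]),
        ]
        measured = Spectrum(axis, 0.7 * m1 + 1.1 * m2 + 0.01 * rng.normal(size=axis.size))
        res = hlp_fit(measured, models, HLPConfig(sigma=0.01, beta_override=1e12))
        refs = [Spectrum(axis, m1), Spectrum(axis, m2)]
        expected = cls_fit(measured, build_design(refs, poly_order=-1)).weights
        np.testing.assert_allclose(res.weights, expected, atol=1e-10)
        for c in res.coeffs:
            np.testing.assert_allclose(c, 0.0, atol=1e-9)

    def test_small_beta_fits_spanned_perturbation_exactly(self, axis, mean_pair, rng, orthonormal_rows):
        # noiseless data whose deviation from the means lies in the component
        # span: with a vanishing penalty the residual must vanish
        m1, m2 = mean_pair
        Z1 = orthonormal_rows(rng, 2, axis.size)
        models = [
            make_model(axis, m1, Z1, [0.5, 0.2]),
            make_model(axis, m2, np.empty((0, axis.size)), []),
        ]
        truth_w, truth_c = 0.6, np.array([0.8, -0.4])
        measured = Spectrum(axis, truth_w * (m1 + truth_c @ Z1) + 1.0 * m2)
        res = hlp_fit(measured, models, HLPConfig(sigma=1.0, beta_override=1e-14, tol=1e-13))
        assert np.linalg.norm(res.residual) < 1e-6
        np.testing.assert_allclose(res.weights, [truth_w, 1.0], atol=1e-5)

    def test_exact_mean_mixture_recovered(self, axis, mean_pair, rng, orthonormal_rows):
        m1, m2 = mean_pair
        models = [
            make_model(axis, m1, orthonormal_rows(rng, 3, axis.size), [0.5, 0.2, 0.1]),
            make_model(axis, m2, orthonormal_rows(rng, 3, axis.size), [0.6, 0.3, 0.05]),
        ]
        measured = Spectrum(axis, 0.3 * m1 + 1.0 * m2)
        res = hlp_fit(measured, models, HLPConfig(sigma=0.01))
        np.testing.assert_allclose(res.weights, [0.3, 1.0], atol=1e-6)
        for c in res.coeffs:
            np.testing.assert_allclose(c, 0.0, atol=1e-5)
        assert abs(res.weights[0] - 0.3) / 0.3 <= 1e-6


class TestSolverBehaviour:
    def test_cost_trace_monotone_on_perturbed_data(self, small_libraries, small_models):
        analyte_lib, background_lib = small_libraries
        ma, mb = small_models
        axis = analyte_lib.axis
        rng = np.random.default_rng(77)
        for _ in range(5):
            i = rng.integers(analyte_lib.n_spectra)
            j = rng.integers(background_lib.n_spectra)
            v = float(2.0 ** -rng.integers(0, 14))
            measured = Spectrum(axis, v * analyte_lib.spectra[i] + background_lib.spectra[j])
            res = hlp_fit(measured, [ma, mb], HLPConfig(sigma=0.002))
            diffs = np.diff(res.cost_trace)
            assert np.all(diffs <= 1e-9 * max(res.cost_trace[0], 1.0))
            assert res.converged

    def test_zero_eigenvalue_component_is_pinned(self, axis, mean_pair, rng, orthonormal_rows):
        m1, m2 = mean_pair
        Z = orthonormal_rows(rng, 2, axis.size)
        model1 = make_model(axis, m1, Z, [0.5, 0.0])  # second mode has zero variance
        model2 = make_model(axis, m2, np.empty((0, axis.size)), [])
        measured = Spectrum(axis, 0.5 * m1 + m2 + 0.01 * rng.normal(size=axis.size))
        res = hlp_fit(measured, [model1, model2], HLPConfig(sigma=0.01))
        # only the non-zero-eigenvalue mode carries a coefficient
        assert res.coeffs[0].size == 1
        assert res.coeffs[1].size == 0

    def test_fitted_equals_weighted_effective_references(self, small_libraries, small_models):
        analyte_lib, background_lib = small_libraries
        axis = analyte_lib.axis
        measured = Spectrum(axis, 0.1 * analyte_lib.spectra[2] + background_lib.spectra[3])
        res = HybridLSPCA(measured, list(small_models), sigma=0.002).fit()
        rebuilt = sum(w * ref for w, ref in zip(res.weights, res.effective_references))
        np.testing.assert_allclose(res.fitted, rebuilt, rtol=1e-10)
        np.testing.assert_allclose(res.fitted + res.residual, measured.intensities, rtol=1e-10)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            HLPConfig(sigma=0.0)
        with pytest.raises(ValueError):
            HLPConfig(sigma=1.0, max_iter=0)
        with pytest.raises(ValueError):
            HLPConfig(sigma=1.0, tol=0.0)


class TestOptimizerOracle:
    def penalized_cost(self, params, m, means, Zs, lams, beta):
        K = means.shape[1]
        W = params[:K]
        C = params[K:]
        x = np.zeros_like(m)
        pen = 0.0
        pos = 0
        for k in range(K):
            Z, lam = Zs[k], lams[k]
            c_k = C[pos : pos + Z.shape[0]]
            pos += Z.shape[0]
            x = x + W[k] * (means[:, k] + Z.T @ c_k)
            if Z.shape[0]:
                pen += np.sum(c_k**2 / lam)
        return np.sum((m - x) ** 2) + beta * pen

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_final_cost_matches_black_box_minimum(self, seed):
        # K=2, P=2, L=12 toy: alternating solver vs multi-start BFGS on
        # the identical penalized cost
        rng = np.random.default_rng(seed)
        L = 12
        axis = np.linspace(400, 1800, L)
        means = np.abs(rng.normal(size=(L, 2))) + 0.5
        Zs, lams = [], []
        for k in range(2):
            q, _ = np.linalg.qr(rng.normal(size=(L, 2)))
            Zs.append(q.T)
            lams.append(np.array([0.4, 0.1]))
        models = [
            make_model(axis, means[:, k], Zs[k], lams[k]) for k in range(2)
        ]
        true_w = np.array([0.4, 1.0])
        perturb = sum(
            true_w[k] * (Zs[k].T @ (0.3 * rng.normal(size=2))) for k in range(2)
        )
        m = means @ true_w + perturb + 0.02 * rng.normal(size=L)
        beta = 0.02**2

        config = HLPConfig(sigma=0.02, n_components=2, tol=1e-14, max_iter=5000)
        res = hlp_fit(Spectrum(axis, m), models, config)

        best = np.inf
        for restart in range(8):
            x0 = rng.normal(scale=0.5, size=6)
            out = minimize(
                self.penalized_cost, x0, args=(m, means, Zs, lams, beta),
                method="BFGS", options={"gtol": 1e-12, "maxiter": 4000},
            )
            best = min(best, out.fun)
        assert res.cost_trace[-1] <= best + 1e-8
        assert abs(res.cost_trace[-1] - best) <= 1e-8
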