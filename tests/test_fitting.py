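"""EM mixture fitting and ML Gaussian estimation."""

import numpy as np
import pytest
from scipy.integrate import quad

from targetkl.density import query_density
from targetkl.fitting import (
    EMConfig,
    GaussianParams,
    GMMParams,
    fit_gaussian_ml,
    fit_gaussian_ml_binned,
    fit_gmm_em,
    gmm_loglik,
    gmm_pdf,
    load_gmm,
    save_gmm,
)
from targetkl.simdata import EmptyDataError, MatrixValidationError


def draw_mixture(rng, weights, means, sds, n, lo=0.0, hi=1.0):
    """Truncated mixture sample by rejection."""
    out = np.empty(0)
    while out.size < n:
        comp = rng.choice(len(weights), size=n, p=weights)
        x = rng.normal(np.asarray(means)[comp], np.asarray(sds)[comp])
        out = np.concatenate([out, x[(x >= lo) & (x <= hi)]])
    return out[:n]


class TestGaussianML:
    def test_two_point_closed_form(self):
        g = fit_gaussian_ml([0.2, 0.4])
        assert g.mu == pytest.approx(0.3) and g.sigma == pytest.approx(0.1)

    def test_constant_vector_is_degenerate(self):
        g = fit_gaussian_ml(np.full(10, 0.7))
        assert g.degenerate and g.sigma == 1e-6 and g.mu == pytest.approx(0.7)

    def test_needs_two_values(self):
        with pytest.raises(EmptyDataError):
            fit_gaussian_ml([0.5])

    def test_divide_by_n_not_n_minus_1(self, rng):
        vals = rng.uniform(0, 1, size=50)
        g = fit_gaussian_ml(vals)
        assert g.sigma == pytest.approx(vals.std(ddof=0))
        assert g.sigma != pytest.approx(vals.std(ddof=1))

    def test_recovery_at_query_fit_scale(self):
        # recover a query-vector Gaussian of realistic location/spread
        # (mu ~ 0.24, sigma ~ 0.075 on the combined [0, 2] score)
        rng = np.random.default_rng(20)
        mu, sigma = 0.24055, 0.07472
        vals = draw_mixture(rng, [1.0], [mu], [sigma], 10000, lo=0.0, hi=2.0)
        g = fit_gaussian_ml(vals)
        assert abs(g.mu - mu) <= 0.003
        assert abs(g.sigma - sigma) <= 0.003

    def test_binned_variant_close_to_raw(self, rng):
        vals = rng.normal(0.5, 0.1, size=5000).clip(0, 2)
        raw = fit_gaussian_ml(vals)
        binned = fit_gaussian_ml_binned(query_density(vals, n_bins=100))
        assert abs(binned.mu - raw.mu) <= 0.02  # one bin width
        assert abs(binned.sigma - raw.sigma) <= 0.02


class TestGMMParams:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(MatrixValidationError):
            GMMParams(weights=[0.5, 0.4], means=[0.2, 0.8], sds=[0.1, 0.1])

    def test_components_sorted_by_mean(self):
        m = GMMParams(weights=[0.3, 0.7], means=[0.8, 0.2], sds=[0.2, 0.1])
        np.testing.assert_array_equal(m.means, [0.2, 0.8])
        np.testing.assert_array_equal(m.weights, [0.7, 0.3])

    def test_mixture_moments(self):
        m = GMMParams(weights=[0.5, 0.5], means=[0.0, 1.0], sds=[0.1, 0.1])
        assert m.mean() == pytest.approx(0.5)
        assert m.sd() == pytest.approx(np.sqrt(0.01 + 0.25))

    def test_json_round_trip(self, tmp_path):
        m = GMMParams(weights=[0.25, 0.75], means=[0.3, 0.6], sds=[0.05, 0.15])
        path = tmp_path / "m.json"
        save_gmm(m, path)
        back = load_gmm(path)
        np.testing.assert_allclose(back.means, m.means)
        np.testing.assert_allclose(back.weights, m.weights)


class TestGMMPdf:
    def test_standard_normal_at_zero(self):
        m = GMMParams(weights=[1.0], means=[0.0], sds=[1.0])
        assert gmm_pdf(m, np.array(0.0)) == pytest.approx(1 / np.sqrt(2 * np.pi))

    def test_integrates_to_one(self):
        m = GMMParams(weights=[0.2, 0.5, 0.3], means=[0.3, 0.5, 0.9], sds=[0.05, 0.1, 0.2])
        total, _ = quad(lambda x: gmm_pdf(m, np.array(x)), -3, 5, limit=200)
        assert abs(total - 1.0) <= 1e-8

    def test_symmetric_mixture_pdf_is_symmetric(self):
        m = GMMParams(weights=[0.5, 0.5], means=[0.3, 0.7], sds=[0.08, 0.08])
        x = np.linspace(0, 1, 101)
        np.testing.assert_allclose(gmm_pdf(m, x), gmm_pdf(m, 1.0 - x)[::-1], atol=1e-12)


class TestEM:
    def test_two_point_k1_closed_form(self):
        m, _ = fit_gmm_em(np.array([0.4, 0.6]), K=1)
        assert m.means[0] == pytest.approx(0.5)
        assert m.sds[0] == pytest.approx(0.1)
        assert m.weights[0] == 1.0

    def test_k1_equals_ml_to_machine_precision(self, rng):
        vals = rng.uniform(0, 2, size=500)
        m, trace = fit_gmm_em(vals, K=1)
        g = fit_gaussian_ml(vals)
        assert m.means[0] == pytest.approx(g.mu, rel=1e-14, abs=1e-14)
        assert m.sds[0] == pytest.approx(g.sigma, rel=1e-12)
        assert trace.converged

    def test_loglik_trace_is_nondecreasing(self, rng):
        vals = draw_mixture(rng, [0.6, 0.4], [0.3, 0.7], [0.08, 0.05], 2000)
        for K in (1, 2, 3):
            _, trace = fit_gmm_em(vals, K, EMConfig(seed=1))
            assert np.all(np.diff(trace.loglik) >= -1e-9)

    def test_two_component_parameter_recovery(self):
        rng = np.random.default_rng(99)
        vals = draw_mixture(rng, [0.5, 0.5], [0.3, 0.7], [0.05, 0.05], 10000)
        m, trace = fit_gmm_em(vals, K=2, config=EMConfig(seed=2))
        np.testing.assert_allclose(m.means, [0.3, 0.7], atol=0.01)
        np.testing.assert_allclose(m.weights, [0.5, 0.5], atol=0.03)
        assert trace.converged

    def test_three_component_recovery_when_well_separated(self):
        rng = np.random.default_rng(5)
        vals = draw_mixture(
            rng, [0.3, 0.4, 0.3], [0.2, 0.5, 0.8], [0.04, 0.04, 0.04], 10000
        )
        m, _ = fit_gmm_em(vals, K=3, config=EMConfig(seed=2))
        np.testing.assert_allclose(m.means, [0.2, 0.5, 0.8], atol=0.01)

    def test_agrees_with_sklearn_reference(self):
        sklearn = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(13)
        vals = np.concatenate(
            [rng.normal(0.3, 0.05, 5000), rng.normal(0.7, 0.05, 5000)]
        )
        ours, _ = fit_gmm_em(vals, K=2, config=EMConfig(seed=3))
        ref = sklearn.GaussianMixture(
            2, tol=1e-8, max_iter=500, random_state=0
        ).fit(vals[:, None])
        np.testing.assert_allclose(ours.means, np.sort(ref.means_.ravel()), atol=1e-4)
        np.testing.assert_allclose(
            ours.sds, np.sqrt(ref.covariances_.ravel())[np.argsort(ref.means_.ravel())],
            atol=1e-4,
        )

    def test_loglik_nondecreasing_in_k_on_skewed_data(self):
        # richer mixtures fit right-skewed similarity data at least as well
        rng = np.random.default_rng(21)
        vals = draw_mixture(rng, [0.8, 0.2], [0.5, 0.85], [0.12, 0.19], 4000, hi=2.0)
        lls = [fit_gmm_em(vals, K, EMConfig(seed=4))[0] for K in (1, 3, 7)]
        scores = [gmm_loglik(m, vals) for m in lls]
        assert scores[0] <= scores[1] + 1e-6 <= scores[2] + 2e-6

    def test_permutation_invariance(self, rng):
        vals = draw_mixture(rng, [0.5, 0.5], [0.3, 0.7], [0.05, 0.05], 2000)
        m1, _ = fit_gmm_em(vals, K=2, config=EMConfig(seed=8))
        m2, _ = fit_gmm_em(rng.permutation(vals), K=2, config=EMConfig(seed=8))
        np.testing.assert_allclose(m1.means, m2.means, atol=1e-6)

    def test_insufficient_data_raises(self):
        with pytest.raises(EmptyDataError):
            fit_gmm_em(np.array([0.1, 0.2]), K=3)

    def test_collapsed_component_floored_and_flagged(self):
        vals = np.concatenate([np.full(50, 0.5), [0.1, 0.9]])
        m, trace = fit_gmm_em(vals, K=2, config=EMConfig(seed=0, max_iter=200))
        assert np.all(m.sds >= 1e-6)

    def test_nonconvergence_flagged_not_fatal(self, rng):
        vals = rng.uniform(0, 1, size=300)
        m, trace = fit_gmm_em(vals, K=3, config=EMConfig(seed=1, max_iter=2))
        assert not trace.converged
        assert "max-iter-reached" in trace.flags
        assert m.K == 3
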