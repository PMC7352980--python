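"""KL divergence: closed form, quadrature agreement, tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from targetkl.divergence import (
    DivergenceTable,
    _padded_interval,
    divergence_table,
    kl_gaussian_closed,
    kl_numeric,
    kl_query_class,
)
from targetkl.fitting import GaussianParams, GMMParams
from targetkl.simdata import MatrixValidationError, UnknownClassError

gauss = st.builds(
    GaussianParams,
    mu=st.floats(min_value=0.05, max_value=1.95),
    sigma=st.floats(min_value=0.01, max_value=0.5),
)


class TestClosedForm:
    def test_identical_gaussians_give_zero(self):
        p = GaussianParams(0.4, 0.1)
        assert kl_gaussian_closed(p, p) == 0.0

    def test_hand_arithmetic_example(self):
        # ln(1/2) + (4 + 0)/2 - 1/2
        val = kl_gaussian_closed(GaussianParams(0.0, 2.0), GaussianParams(0.0, 1.0))
        assert val == pytest.approx(np.log(0.5) + 2.0 - 0.5, abs=1e-12)
        assert val == pytest.approx(0.80685, abs=1e-5)

    def test_query_vs_class_at_published_parameter_scale(self):
        # a narrow query Gaussian against a broad class Gaussian; value
        # verified independently by quadrature below
        q = GaussianParams(0.24055, 0.07472)
        c = GaussianParams(0.5483, 0.1458)
        val = kl_gaussian_closed(q, c)
        assert val == pytest.approx(2.5275, abs=5e-4)
        num = kl_numeric(
            q.pdf, c.pdf, _padded_interval([q.sigma, c.sigma], (0, 2)),
            p_logpdf=q.logpdf, q_logpdf=c.logpdf,
        )
        assert val == pytest.approx(num, abs=1e-6)

    @settings(max_examples=100, derandomize=True)
    @given(p=gauss, q=gauss)
    def test_nonnegative_and_zero_iff_equal(self, p, q):
        d = kl_gaussian_closed(p, q)
        assert d >= -1e-9
        if p.mu == q.mu and p.sigma == q.sigma:
            assert abs(d) <= 1e-9

    def test_monotone_in_mean_gap(self):
        base = GaussianParams(0.5, 0.1)
        gaps = [0.0, 0.05, 0.1, 0.2, 0.4]
        vals = [kl_gaussian_closed(GaussianParams(0.5 + g, 0.07), base) for g in gaps]
        assert np.all(np.diff(vals) > 0)

    def test_asymmetry(self):
        p, q = GaussianParams(0.3, 0.05), GaussianParams(0.6, 0.2)
        assert kl_gaussian_closed(p, q) != pytest.approx(kl_gaussian_closed(q, p))


class TestQuadrature:
    def test_identical_pdfs_give_zero(self):
        p = GaussianParams(0.5, 0.1)
        val = kl_numeric(p.pdf, p.pdf, (-1, 2), p_logpdf=p.logpdf, q_logpdf=p.logpdf)
        assert abs(val) <= 1e-8

    def test_matches_closed_form_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = GaussianParams(rng.uniform(0.1, 0.9), rng.uniform(0.03, 0.3))
            q = GaussianParams(rng.uniform(0.1, 0.9), rng.uniform(0.03, 0.3))
            num = kl_numeric(
                p.pdf, q.pdf, _padded_interval([p.sigma, q.sigma], (0, 2)),
                p_logpdf=p.logpdf, q_logpdf=q.logpdf,
            )
            assert abs(num - kl_gaussian_closed(p, q)) <= 1e-6

    def test_degenerate_mixture_equals_its_gaussian(self):
        g = GaussianParams(0.4, 0.08)
        mix = GMMParams(
            weights=[1.0, 0.0, 0.0], means=[0.4, 0.9, 1.2], sds=[0.08, 0.1, 0.1]
        )
        assert kl_query_class(g, mix) <= 1e-8

    def test_without_logpdfs_uses_floor_path(self):
        p, q = GaussianParams(0.4, 0.1), GaussianParams(0.6, 0.12)
        val = kl_numeric(p.pdf, q.pdf, (-0.5, 1.5))
        assert val == pytest.approx(kl_gaussian_closed(p, q), abs=1e-5)

    def test_rejects_nonpositive_floor(self):
        p = GaussianParams(0.5, 0.1)
        with pytest.raises(MatrixValidationError):
            kl_numeric(p.pdf, p.pdf, (0, 1), floor=0.0)


class TestHistogramDiagnostic:
    def test_histogram_of_model_draws_has_small_divergence(self):
        from targetkl.density import class_density
        from targetkl.divergence import kl_histogram_vs_model

        rng = np.random.default_rng(3)
        g = GaussianParams(1.0, 0.15)
        vals = np.clip(rng.normal(g.mu, g.sigma, 20000), 0, 2)
        d = class_density(vals, n_bins=100)
        # close to its generating model, far from a shifted one
        near = kl_histogram_vs_model(d, g)
        far = kl_histogram_vs_model(d, GaussianParams(0.5, 0.15))
        assert near < 0.05
        assert far > 10 * near


class TestDirections:
    def test_class_to_query_swaps_arguments(self):
        q = GaussianParams(0.3, 0.05)
        c = GMMParams.single(GaussianParams(0.5, 0.1))
        fwd = kl_query_class(q, c, direction="query-to-class")
        rev = kl_query_class(q, c, direction="class-to-query")
        assert fwd == pytest.approx(
            kl_gaussian_closed(q, GaussianParams(0.5, 0.1))
        )
        assert rev == pytest.approx(
            kl_gaussian_closed(GaussianParams(0.5, 0.1), q)
        )

    def test_symmetric_is_mean_of_both(self):
        q = GaussianParams(0.3, 0.05)
        c = GMMParams.single(GaussianParams(0.5, 0.1))
        sym = kl_query_class(q, c, direction="symmetric")
        fwd = kl_query_class(q, c, direction="query-to-class")
        rev = kl_query_class(q, c, direction="class-to-query")
        assert sym == pytest.approx(0.5 * (fwd + rev))


class TestTable:
    def test_single_identical_pair_is_zero(self):
        g = GaussianParams(0.5, 0.1)
        t = divergence_table([("q1", "A", g)], {"A": GMMParams.single(g)})
        assert t.values.shape == (1, 1) and t.values[0, 0] == 0.0

    def test_shape_and_sign_over_four_classes(self, rng):
        classes = {
            lab: GMMParams.single(GaussianParams(mu, 0.1))
            for lab, mu in zip("ABCD", [0.3, 0.45, 0.6, 0.75])
        }
        queries = [
            (f"q{i}", rng.choice(list("ABCD")),
             GaussianParams(rng.uniform(0.2, 0.8), rng.uniform(0.05, 0.2)))
            for i in range(10)
        ]
        t = divergence_table(queries, classes)
        assert t.values.shape == (10, 4)
        assert np.all(t.values >= 0)

    def test_entries_match_scalar_calls(self, rng):
        classes = {
            "A": GMMParams.single(GaussianParams(0.4, 0.1)),
            "B": GMMParams(weights=[0.5, 0.5], means=[0.3, 0.7], sds=[0.1, 0.1]),
        }
        queries = [
            ("q1", "A", GaussianParams(0.35, 0.06)),
            ("q2", "B", GaussianParams(0.6, 0.12)),
        ]
        t = divergence_table(queries, classes, class_order=["A", "B"])
        for i, (_, _, g) in enumerate(queries):
            for j, lab in enumerate(["A", "B"]):
                assert t.values[i, j] == pytest.approx(
                    kl_query_class(g, classes[lab]), abs=1e-12
                )

    def test_per_class_query_fits_are_used_per_column(self):
        classes = {
            "A": GMMParams.single(GaussianParams(0.4, 0.1)),
            "B": GMMParams.single(GaussianParams(0.6, 0.1)),
        }
        fits = {"A": GaussianParams(0.4, 0.1), "B": GaussianParams(0.2, 0.05)}
        t = divergence_table([("q", "A", fits)], classes, class_order=["A", "B"])
        assert t.values[0, 0] == 0.0
        assert t.values[0, 1] == pytest.approx(
            kl_gaussian_closed(fits["B"], GaussianParams(0.6, 0.1))
        )

    def test_missing_class_model_raises(self):
        g = GaussianParams(0.5, 0.1)
        with pytest.raises(UnknownClassError):
            divergence_table(
                [("q", "A", g)], {"A": GMMParams.single(g)}, class_order=["A", "B"]
            )

    def test_round_trip_through_tsv(self, tmp_path, rng):
        classes = {lab: GMMParams.single(GaussianParams(mu, 0.1))
                   for lab, mu in zip("AB", [0.4, 0.6])}
        queries = [("q1", "A", GaussianParams(0.35, 0.06)),
                   ("q2", "B", GaussianParams(0.66, 0.09))]
        t = divergence_table(queries, classes)
        path = tmp_path / "t.tsv"
        t.write(path)
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == ["query_id", "true_class", "A", "B"]
        np.testing.assert_allclose(df[["A", "B"]].to_numpy(), t.values, atol=1e-6)
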