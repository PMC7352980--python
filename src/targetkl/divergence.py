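"""Kullback-Leibler divergence between query and class distributions.

The relevance of a query compound to a target class is scored by the K-L
divergence D(query || class) between the query's fitted Gaussian and the
class's fitted mixture.  For a one-component class model the Gaussian-
Gaussian closed form applies:

    D(N(m_i, s_i) || N(m_j, s_j))
        = ln(s_j / s_i) + (s_i^2 + (m_i - m_j)^2) / (2 s_j^2) - 1/2

For K > 1 there is no closed form and the divergence is computed by
deterministic trapezoidal quadrature of p ln(p/q) over the score range
padded by six standard deviations, with the denominator density floored
before the logarithm to keep the integrand finite in the tails.

The divergence is asymmetric; the default direction puts the query first
(the query's distribution is measured against the class's representative
distribution), with class-to-query and symmetrized variants available.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fitting import GaussianParams, GMMParams
from .simdata import COMBO_RANGE, MatrixValidationError, UnknownClassError

__all__ = [
    "DEFAULT_QUAD_POINTS",
    "DEFAULT_PROB_FLOOR",
    "kl_gaussian_closed",
    "kl_numeric",
    "kl_query_class",
    "kl_histogram_vs_model",
    "DivergenceTable",
    "divergence_table",
]

DEFAULT_QUAD_POINTS = 4096
DEFAULT_PROB_FLOOR = 1e-300
#: Half-width of the quadrature padding, in pooled standard deviations.
PAD_SDS = 6.0


def kl_gaussian_closed(p: GaussianParams, q: GaussianParams) -> float:
    """Closed-form K-L divergence D(p || q) between two Gaussians (nats)."""
    if p.sigma <= 0 or q.sigma <= 0:
        raise MatrixValidationError("Gaussian sigmas must be positive")
    return float(
        np.log(q.sigma / p.sigma)
        + (p.sigma**2 + (p.mu - q.mu) ** 2) / (2.0 * q.sigma**2)
        - 0.5
    )


def kl_numeric(
    p_pdf: Callable[[np.ndarray], np.ndarray],
    q_pdf: Callable[[np.ndarray], np.ndarray],
    interval: tuple[float, float],
    n_points: int = DEFAULT_QUAD_POINTS,
    floor: float = DEFAULT_PROB_FLOOR,
    p_logpdf: Callable[[np.ndarray], np.ndarray] | None = None,
    q_logpdf: Callable[[np.ndarray], np.ndarray] | None = None,
) -> float:
    """K-L divergence by trapezoidal quadrature of p ln(p/q) (nats).

    When log-density callables are supplied they are used directly, which
    keeps the integrand accurate in tails where the plain densities
    underflow; otherwise the densities are floored at ``floor`` before the
    logarithm.  Where ``p`` is zero the integrand is taken as zero (its
    limiting value).  Tiny negative results from quadrature error are
    clipped to zero.
    """
    if floor <= 0:
        raise MatrixValidationError("probability floor must be positive")
    lo, hi = interval
    x = np.linspace(lo, hi, n_points)
    if p_logpdf is not None and q_logpdf is not None:
        lp = np.asarray(p_logpdf(x), dtype=float)
        lq = np.asarray(q_logpdf(x), dtype=float)
        if np.any(np.isnan(lp)) or np.any(np.isnan(lq)):
            raise FloatingPointError("non-finite log-pdf evaluation in quadrature")
        p = np.exp(lp)
        integrand = np.where(p > 0, p * (lp - lq), 0.0)
    else:
        p = np.asarray(p_pdf(x), dtype=float)
        q = np.asarray(q_pdf(x), dtype=float)
        if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
            raise FloatingPointError("non-finite pdf evaluation in quadrature")
        q = np.maximum(q, floor)
        integrand = np.where(
            p > 0, p * (np.log(np.maximum(p, floor)) - np.log(q)), 0.0
        )
    val = float(np.trapezoid(integrand, x))
    return max(val, 0.0)


def kl_histogram_vs_model(
    density,
    model: "GMMParams | GaussianParams",
    floor: float = DEFAULT_PROB_FLOOR,
) -> float:
    """Diagnostic divergence of a binned empirical density from a model.

    Approximates D(histogram || model) as sum over bins of
    mass * ln(height / model_pdf(midpoint)); useful for judging how well
    a fitted Q-distribution reproduces the raw class histogram.  Not used
    in the discrimination pipeline, which compares fitted forms.
    """
    from .density import HistogramDensity  # local import avoids cycle

    if not isinstance(density, HistogramDensity):
        raise MatrixValidationError("expected a HistogramDensity")
    if isinstance(model, GaussianParams):
        model = GMMParams.single(model)
    mid = density.midpoints()
    heights = density.heights()
    q = np.maximum(np.asarray(model.pdf(mid), dtype=float), floor)
    mask = density.masses > 0
    val = float(np.sum(density.masses[mask] * np.log(heights[mask] / q[mask])))
    return max(val, 0.0)


def _padded_interval(
    sds: Sequence[float], score_range: tuple[float, float]
) -> tuple[float, float]:
    pad = PAD_SDS * float(max(sds))
    return score_range[0] - pad, score_range[1] + pad


def kl_query_class(
    query: GaussianParams,
    class_model: GMMParams | GaussianParams,
    score_range: tuple[float, float] = COMBO_RANGE,
    direction: str = "query-to-class",
    n_points: int = DEFAULT_QUAD_POINTS,
    floor: float = DEFAULT_PROB_FLOOR,
) -> float:
    """Divergence between one query Gaussian and one class model.

    Uses the closed form when the class model is (or reduces to) a single
    Gaussian and the requested direction permits it; otherwise quadrature
    over the padded score range.  ``direction`` is one of
    ``"query-to-class"`` (default), ``"class-to-query"``, ``"symmetric"``
    (mean of both directions).
    """
    if isinstance(class_model, GaussianParams):
        class_model = GMMParams.single(class_model)
    if direction not in {"query-to-class", "class-to-query", "symmetric"}:
        raise MatrixValidationError(f"unknown direction {direction!r}")
    if class_model.K == 1:
        cg = GaussianParams(
            mu=float(class_model.means[0]), sigma=float(class_model.sds[0])
        )
        if direction == "query-to-class":
            return kl_gaussian_closed(query, cg)
        if direction == "class-to-query":
            return kl_gaussian_closed(cg, query)
        return 0.5 * (kl_gaussian_closed(query, cg) + kl_gaussian_closed(cg, query))
    interval = _padded_interval(
        [query.sigma, *class_model.sds.tolist()], score_range
    )
    fwd = lambda: kl_numeric(
        query.pdf, class_model.pdf, interval, n_points, floor,
        p_logpdf=query.logpdf, q_logpdf=class_model.logpdf,
    )
    rev = lambda: kl_numeric(
        class_model.pdf, query.pdf, interval, n_points, floor,
        p_logpdf=class_model.logpdf, q_logpdf=query.logpdf,
    )
    if direction == "query-to-class":
        return fwd()
    if direction == "class-to-query":
        return rev()
    return 0.5 * (fwd() + rev())


@dataclass(frozen=True)
class DivergenceTable:
    """Per-query, per-class divergence matrix (nats).

    Rows are queries (with their annotated true class); columns follow
    ``class_labels`` in class-number order.
    """

    query_ids: list[str]
    query_classes: list[str]
    class_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, float))
        if self.values.shape != (len(self.query_ids), len(self.class_labels)):
            raise MatrixValidationError("divergence table shape mismatch")
        if len(self.query_classes) != len(self.query_ids):
            raise MatrixValidationError("query_classes length mismatch")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < -1e-9):
            raise MatrixValidationError(
                "divergences must be finite and non-negative"
            )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.class_labels)
        df.insert(0, "query_id", self.query_ids)
        df.insert(1, "true_class", self.query_classes)
        return df

    def write(self, path: str | Path, delimiter: str = "\t") -> None:
        self.to_dataframe().to_csv(path, sep=delimiter, index=False, float_format="%.6f")


def divergence_table(
    queries: Sequence[tuple[str, str, GaussianParams | Mapping[str, GaussianParams]]],
    classes: Mapping[str, GMMParams],
    class_order: Sequence[str] | None = None,
    score_range: tuple[float, float] = COMBO_RANGE,
    direction: str = "query-to-class",
) -> DivergenceTable:
    """Divergence of every query against every class model.

    ``queries`` are (query_id, true_class_label, fit) triples where the fit
    is either one Gaussian, or — matching the full pipeline, where a query
    is fitted separately on its similarity vector against each target
    class — a mapping from class label to that per-class Gaussian.
    ``classes`` maps class label to its fitted Q-model; ``class_order``
    fixes the column order (defaults to mapping order).
    """
    labels = list(class_order) if class_order is not None else list(classes)
    for lab in labels:
        if lab not in classes:
            raise UnknownClassError(f"no fitted model for class {lab!r}")
    out = np.empty((len(queries), len(labels)), dtype=float)
    for i, (qid, _, g) in enumerate(queries):
        for j, lab in enumerate(labels):
            if isinstance(g, GaussianParams):
                g_n = g
            else:
                if lab not in g:
                    raise UnknownClassError(
                        f"query {qid!r} has no fit against class {lab!r}"
                    )
                g_n = g[lab]
            out[i, j] = kl_query_class(
                g_n, classes[lab], score_range=score_range, direction=direction
            )
    return DivergenceTable(
        query_ids=[q[0] for q in queries],
        query_classes=[q[1] for q in queries],
        class_labels=labels,
        values=out,
    )
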