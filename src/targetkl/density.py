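"""Binned probability densities of similarity values.

Both the intra-class ligand-pair similarities and a single query's
similarity vector are summarized as histograms over the score range before
(or alongside) parametric fitting.  Class histograms default to 1000 bins
over the combined-score range [0, 2]; query histograms, built from far
fewer values, default to 100 bins.

A :class:`HistogramDensity` stores probability *mass* per bin (summing to
one); the density *height* at a bin is mass / bin width and is exposed via
:meth:`HistogramDensity.heights` for plotting against fitted curves.
Bins follow the half-open convention ``[x_k, x_{k+1})`` with the final bin
closed, so a value at the range maximum is counted exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .simdata import COMBO_RANGE, EmptyDataError, MatrixValidationError, QueryVector

__all__ = [
    "HistogramDensity",
    "class_density",
    "query_density",
    "write_density",
]

DEFAULT_CLASS_BINS = 1000
DEFAULT_QUERY_BINS = 100


@dataclass(frozen=True)
class HistogramDensity:
    """Probability mass function over equal-width bins of the score range."""

    bin_edges: np.ndarray
    masses: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, float))
        object.__setattr__(self, "masses", np.asarray(self.masses, float))
        if self.masses.size != self.bin_edges.size - 1:
            raise MatrixValidationError(
                "masses must have one fewer element than bin_edges"
            )
        if np.any(self.masses < 0):
            raise MatrixValidationError("negative bin mass")
        if abs(self.masses.sum() - 1.0) > 1e-12:
            raise MatrixValidationError(
                f"bin masses sum to {self.masses.sum()!r}, not 1"
            )
        if np.any(np.diff(self.bin_edges) <= 0):
            raise MatrixValidationError("bin_edges must be strictly increasing")

    @property
    def delta_x(self) -> float:
        """Bin width (bins are equal width)."""
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def n_bins(self) -> int:
        return self.masses.size

    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def heights(self) -> np.ndarray:
        """Density heights: mass per bin divided by bin width."""
        return self.masses / self.delta_x

    def mean(self) -> float:
        """Mean of the binned distribution (midpoint-weighted)."""
        return float(np.sum(self.midpoints() * self.masses))

    def sd(self) -> float:
        """Standard deviation of the binned distribution."""
        mu = self.mean()
        return float(np.sqrt(np.sum(self.masses * (self.midpoints() - mu) ** 2)))


def class_density(
    values: np.ndarray,
    n_bins: int = DEFAULT_CLASS_BINS,
    score_range: tuple[float, float] = COMBO_RANGE,
) -> HistogramDensity:
    """Histogram density of intra-class ligand-pair similarities.

    ``masses[k]`` is the fraction of values in ``[x_k, x_{k+1})`` (final
    bin right-closed), so the masses sum to one.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise EmptyDataError("cannot build a density from an empty sample")
    if n_bins < 2:
        raise MatrixValidationError("n_bins must be at least 2")
    lo, hi = score_range
    if values.min() < lo or values.max() > hi:
        raise MatrixValidationError(
            f"values outside score range [{lo}, {hi}]"
        )
    counts, edges = np.histogram(values, bins=n_bins, range=score_range)
    return HistogramDensity(
        bin_edges=edges,
        masses=counts / values.size,
        n_samples=values.size,
    )


def query_density(
    vector: QueryVector | np.ndarray,
    n_bins: int = DEFAULT_QUERY_BINS,
    score_range: tuple[float, float] | None = None,
) -> HistogramDensity:
    """Histogram density of one query's similarity vector.

    Same contract as :func:`class_density`; the default bin count is
    coarser because a query vector has as many values as the target class
    has ligands, typically orders of magnitude fewer than the class block.
    """
    if isinstance(vector, QueryVector):
        if score_range is None:
            score_range = vector.score_range
        values = vector.values
    else:
        values = np.asarray(vector, dtype=float)
        if score_range is None:
            score_range = COMBO_RANGE
    return class_density(values, n_bins=n_bins, score_range=score_range)


def write_density(density: HistogramDensity, path: str | Path) -> None:
    """Export as two-column delimited text: bin midpoint, probability mass."""
    arr = np.column_stack([density.midpoints(), density.masses])
    np.savetxt(path, arr, fmt="%.10g", delimiter="\t", header="midpoint\tmass")
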