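"""Target assignment, assignment probabilities and the feasibility index.

Given a table of query-to-class divergences, each query is assigned the
class minimizing its divergence (ties broken toward the lowest class
number).  Aggregating assignments by the queries' annotated classes gives
the M x M assignment probability matrix P(assigned = i | true = m), from
which two discriminability summaries follow:

* the *necessary condition* per class: the diagonal probability is at
  least as large as every off-diagonal entry of its row — queries of the
  class are recovered more often than they are confused with any single
  other class;
* the *feasibility index* F_m built from the self-assignment odds
  P/(1-P).  Two conventions are implemented: ``"odds"`` is the plain odds
  ratio, while the default ``"sqrt-odds"`` is its square root, the
  convention that matches published per-class feasibility values
  (see docs/methods.md for the discrepancy between the two).

Empirical cumulative divergence curves per (query-class, target-class)
pair support the same comparison graphically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .divergence import DivergenceTable
from .simdata import EmptyDataError, MatrixValidationError

__all__ = [
    "assign_class",
    "probability_matrix",
    "necessary_condition",
    "feasibility_index",
    "cumulative_divergence",
    "DiscriminationReport",
    "discriminate",
]


def assign_class(divergence_row: np.ndarray) -> int:
    """1-based class number minimizing the divergence (ties -> lowest)."""
    row = np.asarray(divergence_row, dtype=float).ravel()
    if row.size == 0:
        raise EmptyDataError("cannot assign from an empty divergence row")
    if np.any(np.isnan(row)):
        raise FloatingPointError("NaN in divergence row")
    return int(np.argmin(row)) + 1


def probability_matrix(
    true_classes: Sequence[int], assignments: Sequence[int], n_classes: int
) -> np.ndarray:
    """Row-stochastic matrix P[m-1, i-1] = P(assigned = i | true = m).

    ``true_classes`` and ``assignments`` are 1-based class numbers; every
    class 1..n_classes must contribute at least one query.
    """
    true_arr = np.asarray(true_classes, dtype=int)
    assn = np.asarray(assignments, dtype=int)
    if true_arr.shape != assn.shape:
        raise MatrixValidationError("true/assigned class arrays must match")
    P = np.zeros((n_classes, n_classes), dtype=float)
    for m in range(1, n_classes + 1):
        mask = true_arr == m
        if not mask.any():
            raise EmptyDataError(f"class {m} has no queries")
        counts = np.bincount(assn[mask], minlength=n_classes + 1)[1:]
        P[m - 1] = counts / mask.sum()
    return P


def necessary_condition(prob_matrix: np.ndarray) -> np.ndarray:
    """Per-class flag: diagonal probability >= every off-diagonal in its row."""
    P = np.asarray(prob_matrix, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise MatrixValidationError("probability matrix must be square")
    if np.any(P < 0) or np.any(P > 1):
        raise MatrixValidationError("probabilities must lie in [0, 1]")
    M = P.shape[0]
    out = np.empty(M, dtype=bool)
    for m in range(M):
        off = np.delete(P[m], m)
        out[m] = P[m, m] >= (off.max() if off.size else 0.0)
    return out


def feasibility_index(p_mm: float, mode: str = "sqrt-odds") -> float:
    """Class discriminability from the self-assignment probability.

    ``"odds"`` returns the odds P/(1-P); ``"sqrt-odds"`` (default) returns
    sqrt(P/(1-P)).  ``p_mm = 1`` yields ``inf`` (perfect self-assignment).
    """
    if mode not in {"odds", "sqrt-odds"}:
        raise MatrixValidationError(f"unknown feasibility mode {mode!r}")
    p = float(p_mm)
    if not 0.0 <= p <= 1.0:
        raise MatrixValidationError(f"probability {p!r} outside [0, 1]")
    if p == 1.0:
        return float("inf")
    odds = p / (1.0 - p)
    return float(np.sqrt(odds)) if mode == "sqrt-odds" else float(odds)


def cumulative_divergence(divergences: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF of a divergence sample: (sorted values, rank / n)."""
    d = np.asarray(divergences, dtype=float).ravel()
    if d.size == 0:
        raise EmptyDataError("cannot build a CDF from an empty sample")
    if np.any(~np.isfinite(d)):
        raise FloatingPointError("non-finite divergence in CDF input")
    s = np.sort(d)
    return s, np.arange(1, d.size + 1) / d.size


@dataclass(frozen=True)
class DiscriminationReport:
    """Assignments, probability matrix, condition flags and feasibility."""

    class_labels: list[str]
    query_ids: list[str]
    assignments: np.ndarray
    prob_matrix: np.ndarray
    necessary_ok: np.ndarray
    feasibility: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        rows = np.asarray(self.prob_matrix).sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-10):
            raise MatrixValidationError("probability matrix rows must sum to 1")

    def to_dict(self) -> dict:
        return {
            "class_labels": list(self.class_labels),
            "mode": self.mode,
            "assignments": {
                q: int(a) for q, a in zip(self.query_ids, self.assignments)
            },
            "prob_matrix": [[float(v) for v in row] for row in self.prob_matrix],
            "necessary_ok": [bool(v) for v in self.necessary_ok],
            "feasibility": [float(v) for v in self.feasibility],
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def discriminate(
    table: DivergenceTable, mode: str = "sqrt-odds"
) -> DiscriminationReport:
    """Full discrimination summary from a divergence table.

    Queries whose true class is not among the table's class columns (for
    example an unannotated external compound) are assigned but excluded
    from the probability matrix.
    """
    labels = table.class_labels
    assignments = np.array([assign_class(row) for row in table.values], dtype=int)
    in_panel = [qc in labels for qc in table.query_classes]
    if not any(in_panel):
        raise EmptyDataError("no query belongs to any class in the table")
    true_nums = np.array(
        [labels.index(qc) + 1 for qc, ok in zip(table.query_classes, in_panel) if ok],
        dtype=int,
    )
    panel_assign = assignments[np.asarray(in_panel)]
    P = probability_matrix(true_nums, panel_assign, len(labels))
    ok = necessary_condition(P)
    feas = np.array(
        [feasibility_index(P[m, m], mode=mode) for m in range(len(labels))]
    )
    return DiscriminationReport(
        class_labels=list(labels),
        query_ids=list(table.query_ids),
        assignments=assignments,
        prob_matrix=P,
        necessary_ok=ok,
        feasibility=feas,
        mode=mode,
    )
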