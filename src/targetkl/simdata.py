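"""Similarity-matrix data model, I/O and slicing.

The raw material of chemocentric target prediction is a matrix of
Jaccard-Tanimoto coefficients between ligand conformers.  Rows and columns
are conformer identifiers; a companion annotation maps each identifier to
its drug-target class.  Entries live in a closed score range: ``[0, 1]``
for a single feature (shape only) or ``[0, 2]`` for the combined
shape+color score.  Matrices are generally *not* symmetric, because the
3D overlay of a pair (A, B) is optimized independently of (B, A), so no
symmetrization is applied by default.

Two slicing operations feed the rest of the pipeline:

* :func:`class_block` — the square intra-class submatrix whose entries are
  the ligand-pair similarities within one target class (the sample behind
  the class's representative distribution);
* :func:`extract_query_vector` — one column of similarities between a
  single query conformer and every ligand of a target class (the sample
  behind the query's Gaussian fit).

Self-pairs sit at the score-range maximum by construction and are excluded
by default from both slices so they cannot distort the fitted
distributions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COMBO_RANGE",
    "SINGLE_RANGE",
    "SimDataError",
    "MatrixValidationError",
    "MatrixParseError",
    "UnknownIDError",
    "UnknownClassError",
    "EmptyDataError",
    "ClassAnnotation",
    "SimilarityMatrix",
    "ClassBlock",
    "QueryVector",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_annotation",
    "write_annotation",
    "class_block",
    "extract_query_vector",
    "symmetrize",
]

#: Score range of the combined shape + color Tanimoto score.
COMBO_RANGE: tuple[float, float] = (0.0, 2.0)
#: Score range of a single-feature Tanimoto score.
SINGLE_RANGE: tuple[float, float] = (0.0, 1.0)


class SimDataError(ValueError):
    """Base error for similarity-matrix handling."""


class MatrixValidationError(SimDataError):
    """An entry or shape violates the matrix invariants."""


class MatrixParseError(SimDataError):
    """A cell of a delimited matrix file could not be parsed as a number."""


class UnknownIDError(SimDataError, KeyError):
    """A ligand identifier is absent from the matrix or annotation."""


class UnknownClassError(SimDataError, KeyError):
    """A class label or class number is not present."""


class EmptyDataError(SimDataError):
    """An operation would produce an empty sample."""


@dataclass(frozen=True)
class ClassAnnotation:
    """Mapping from ligand IDs to target classes, with 1-based numbering.

    Class numbers are assigned by first appearance in ``labels`` (or by the
    explicit ``order``), forming a bijection between labels and
    ``1..M``.  Duplicate conformers of one compound share an ID and hence a
    class; they are still distinct matrix rows.
    """

    labels: dict[str, str]
    order: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        seen: list[str] = []
        for lab in self.labels.values():
            if lab not in seen:
                seen.append(lab)
        if not self.order:
            object.__setattr__(self, "order", tuple(seen))
        else:
            missing = set(seen) - set(self.order)
            if missing:
                raise UnknownClassError(
                    f"class order omits labels {sorted(missing)}"
                )

    @property
    def n_classes(self) -> int:
        return len(self.order)

    def class_of(self, ligand_id: str) -> str:
        try:
            return self.labels[ligand_id]
        except KeyError:
            raise UnknownIDError(f"ligand {ligand_id!r} has no class annotation")

    def number(self, label: str) -> int:
        """1-based class number of ``label``."""
        try:
            return self.order.index(label) + 1
        except ValueError:
            raise UnknownClassError(f"unknown class label {label!r}")

    def label(self, number: int) -> str:
        """Class label of 1-based class ``number``."""
        if not 1 <= number <= self.n_classes:
            raise UnknownClassError(
                f"class number {number} outside 1..{self.n_classes}"
            )
        return self.order[number - 1]

    def resolve(self, cls: int | str) -> str:
        """Accept a label or a 1-based number; return the label."""
        if isinstance(cls, str):
            if cls not in self.order:
                raise UnknownClassError(f"unknown class label {cls!r}")
            return cls
        return self.label(int(cls))

    def members(self, label: str) -> list[str]:
        """Ligand IDs annotated with ``label``, in insertion order."""
        if label not in self.order:
            raise UnknownClassError(f"unknown class label {label!r}")
        return [i for i, lab in self.labels.items() if lab == label]


@dataclass
class SimilarityMatrix:
    """Rectangular array of Tanimoto coefficients with ID and class labels.

    ``row_class``/``col_class`` may be empty strings when no annotation has
    been attached; class-aware operations then raise.
    """

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    row_class: list[str]
    col_class: list[str]
    score_range: tuple[float, float] = COMBO_RANGE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MatrixValidationError("values must be a 2-D array")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise MatrixValidationError(
                f"shape {self.values.shape} does not match "
                f"({len(self.row_ids)}, {len(self.col_ids)}) IDs"
            )
        if len(self.row_class) != len(self.row_ids):
            raise MatrixValidationError("row_class length mismatch")
        if len(self.col_class) != len(self.col_ids):
            raise MatrixValidationError("col_class length mismatch")
        lo, hi = self.score_range
        if not np.all(np.isfinite(self.values)):
            raise MatrixValidationError("matrix contains non-finite entries")
        if self.values.size and (
            self.values.min() < lo or self.values.max() > hi
        ):
            bad = np.argwhere((self.values < lo) | (self.values > hi))[0]
            i, j = int(bad[0]), int(bad[1])
            raise MatrixValidationError(
                f"entry {self.values[i, j]!r} at ({self.row_ids[i]!r}, "
                f"{self.col_ids[j]!r}) outside score range [{lo}, {hi}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.row_ids), columns=list(self.col_ids)
        )

    def with_annotation(self, annotation: ClassAnnotation) -> "SimilarityMatrix":
        """Return a copy whose class labels come from ``annotation``."""
        return SimilarityMatrix(
            values=self.values.copy(),
            row_ids=list(self.row_ids),
            col_ids=list(self.col_ids),
            row_class=[annotation.class_of(i) for i in self.row_ids],
            col_class=[annotation.class_of(i) for i in self.col_ids],
            score_range=self.score_range,
        )


@dataclass(frozen=True)
class ClassBlock:
    """Intra-class submatrix together with its diagonal convention."""

    matrix: SimilarityMatrix
    include_diagonal: bool = False

    def entries(self) -> np.ndarray:
        """Flat multiset of similarity entries feeding the class density."""
        v = self.matrix.values
        if self.include_diagonal:
            return v.ravel().copy()
        n = v.shape[0]
        mask = ~np.eye(n, dtype=bool)
        return v[mask]

    @property
    def n_entries(self) -> int:
        n = self.matrix.shape[0]
        return n * n if self.include_diagonal else n * (n - 1)


@dataclass(frozen=True)
class QueryVector:
    """Similarities between one query conformer and a target class's ligands."""

    query_id: str
    query_class: str
    target_class: str
    values: np.ndarray
    score_range: tuple[float, float] = COMBO_RANGE

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float).ravel()
        )
        lo, hi = self.score_range
        if self.values.size and (
            self.values.min() < lo or self.values.max() > hi
        ):
            raise MatrixValidationError(
                f"query vector for {self.query_id!r} has entries outside "
                f"[{lo}, {hi}]"
            )

    def __len__(self) -> int:
        return self.values.size


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_similarity_matrix(
    path: str | Path,
    annotation: ClassAnnotation | None = None,
    score_range: tuple[float, float] = COMBO_RANGE,
    delimiter: str | None = None,
) -> SimilarityMatrix:
    """Read a delimited similarity matrix with an ID header row and column.

    Parameters
    ----------
    path
        Comma- or tab-delimited text file; first row and first column hold
        ligand IDs.
    annotation
        Optional class annotation; when given, every matrix ID must be
        annotated and class labels are attached.
    score_range
        Closed interval every entry must lie in (default combined-score
        ``[0, 2]``).
    delimiter
        Explicit delimiter; sniffed from the header line when ``None``.
    """
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=float)
    it = np.nditer(raw, flags=["multi_index", "refs_ok"])
    for cell in it:
        i, j = it.multi_index
        try:
            values[i, j] = float(cell[()])
        except (TypeError, ValueError):
            raise MatrixParseError(
                f"non-numeric cell {cell[()]!r} at row {row_ids[i]!r}, "
                f"column {col_ids[j]!r} in {path}"
            )
    if annotation is not None:
        row_class = [annotation.class_of(i) for i in row_ids]
        col_class = [annotation.class_of(c) for c in col_ids]
    else:
        row_class = [""] * len(row_ids)
        col_class = [""] * len(col_ids)
    return SimilarityMatrix(
        values=values,
        row_ids=row_ids,
        col_ids=col_ids,
        row_class=row_class,
        col_class=col_class,
        score_range=score_range,
    )


def write_similarity_matrix(
    matrix: SimilarityMatrix,
    path: str | Path,
    precision: int = 6,
    delimiter: str = ",",
) -> None:
    """Write the matrix as delimited text with fixed decimal precision."""
    df = matrix.to_dataframe()
    df.to_csv(path, sep=delimiter, float_format=f"%.{precision}f")


def read_annotation(path: str | Path, delimiter: str | None = None) -> ClassAnnotation:
    """Read a two-column (ligand_id, class_label) annotation table.

    A header line is detected and skipped when its second field is the
    literal ``class`` or ``class_label``.
    """
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    labels: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        for row_no, row in enumerate(reader):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise MatrixParseError(
                    f"annotation line {row_no + 1} in {path} has fewer than "
                    f"two fields: {row!r}"
                )
            lig, lab = row[0].strip(), row[1].strip()
            if row_no == 0 and lab.lower() in {"class", "class_label", "target"}:
                continue
            labels[lig] = lab
    if not labels:
        raise EmptyDataError(f"annotation file {path} is empty")
    return ClassAnnotation(labels=labels)


def write_annotation(
    annotation: ClassAnnotation, path: str | Path, delimiter: str = "\t"
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["ligand_id", "class_label"])
        for lig, lab in annotation.labels.items():
            writer.writerow([lig, lab])


def _class_indices(ids: Sequence[str], classes: Sequence[str], label: str) -> np.ndarray:
    idx = np.array([k for k, lab in enumerate(classes) if lab == label], dtype=int)
    return idx


def class_block(
    matrix: SimilarityMatrix,
    cls: int | str,
    annotation: ClassAnnotation | None = None,
    include_diagonal: bool = False,
) -> ClassBlock:
    """Intra-class block of ligand-pair similarities for one target class.

    ``cls`` may be a class label or a 1-based class number (the latter needs
    ``annotation`` for the numbering).  The returned block keeps the full
    square submatrix; self-pairs on its diagonal are excluded from
    :meth:`ClassBlock.entries` unless ``include_diagonal`` is set.
    """
    if annotation is not None:
        label = annotation.resolve(cls)
    elif isinstance(cls, str):
        label = cls
    else:
        raise UnknownClassError(
            "numeric class requires an annotation for the numbering"
        )
    rows = _class_indices(matrix.row_ids, matrix.row_class, label)
    cols = _class_indices(matrix.col_ids, matrix.col_class, label)
    if rows.size == 0 or cols.size == 0:
        raise UnknownClassError(f"class {label!r} not present in matrix")
    sub = SimilarityMatrix(
        values=matrix.values[np.ix_(rows, cols)],
        row_ids=[matrix.row_ids[i] for i in rows],
        col_ids=[matrix.col_ids[j] for j in cols],
        row_class=[label] * rows.size,
        col_class=[label] * cols.size,
        score_range=matrix.score_range,
    )
    if not include_diagonal and min(rows.size, cols.size) < 2:
        raise EmptyDataError(
            f"class {label!r} has fewer than 2 members; no off-diagonal pairs"
        )
    return ClassBlock(matrix=sub, include_diagonal=include_diagonal)


def extract_query_vector(
    matrix: SimilarityMatrix,
    query_id: str,
    target_class: int | str,
    annotation: ClassAnnotation | None = None,
) -> QueryVector:
    """Column of similarities between one query and a target class's ligands.

    The query must appear among the matrix columns.  When the query itself
    belongs to the target class, rows sharing its ID (self-pairs) are
    dropped.
    """
    if annotation is not None:
        label = annotation.resolve(target_class)
    elif isinstance(target_class, str):
        label = target_class
    else:
        raise UnknownClassError(
            "numeric class requires an annotation for the numbering"
        )
    try:
        col = matrix.col_ids.index(query_id)
    except ValueError:
        raise UnknownIDError(f"query {query_id!r} not among matrix columns")
    query_class = matrix.col_class[col]
    rows = _class_indices(matrix.row_ids, matrix.row_class, label)
    if rows.size == 0:
        raise UnknownClassError(f"class {label!r} not present in matrix rows")
    if query_class == label:
        rows = np.array(
            [i for i in rows if matrix.row_ids[i] != query_id], dtype=int
        )
    if rows.size == 0:
        raise EmptyDataError(
            f"no non-self similarities between {query_id!r} and class {label!r}"
        )
    return QueryVector(
        query_id=query_id,
        query_class=query_class,
        target_class=label,
        values=matrix.values[rows, col],
        score_range=matrix.score_range,
    )


def symmetrize(matrix: SimilarityMatrix) -> SimilarityMatrix:
    """Average a square matrix with its transpose (optional mode).

    The default pipeline keeps matrices asymmetric because the pairwise 3D
    overlays (A, B) and (B, A) are optimized independently; this helper is
    for users who prefer a symmetric similarity.
    """
    if matrix.shape[0] != matrix.shape[1]:
        raise MatrixValidationError("symmetrize requires a square matrix")
    if matrix.row_ids != matrix.col_ids:
        raise MatrixValidationError("symmetrize requires matching row/col IDs")
    return SimilarityMatrix(
        values=0.5 * (matrix.values + matrix.values.T),
        row_ids=list(matrix.row_ids),
        col_ids=list(matrix.col_ids),
        row_class=list(matrix.row_class),
        col_class=list(matrix.col_class),
        score_range=matrix.score_range,
    )
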