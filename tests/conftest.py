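"""Shared fixtures: small random matrices and session-scoped experiments."""

import numpy as np
import pytest

from targetkl.simdata import ClassAnnotation, SimilarityMatrix
from targetkl.synthetic import null_spec, recovery_experiment, separated_spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_labeled_matrix(rng, class_sizes, score_range=(0.0, 2.0)):
    """Random labeled square matrix with the given per-class sizes."""
    labels = [f"T{k + 1}" for k in range(len(class_sizes))]
    ids, classes = [], []
    for lab, n in zip(labels, class_sizes):
        for i in range(n):
            ids.append(f"{lab}_{i}")
            classes.append(lab)
    n_total = len(ids)
    lo, hi = score_range
    values = rng.uniform(lo, hi, size=(n_total, n_total))
    np.fill_diagonal(values, hi)
    return SimilarityMatrix(
        values=values,
        row_ids=ids,
        col_ids=list(ids),
        row_class=classes,
        col_class=list(classes),
        score_range=score_range,
    )


@pytest.fixture
def labeled_matrix(rng):
    """4-class matrix with unequal class sizes (3, 4, 5, 6)."""
    return make_labeled_matrix(rng, [3, 4, 5, 6])


@pytest.fixture
def annotation(labeled_matrix):
    return ClassAnnotation(
        labels=dict(zip(labeled_matrix.row_ids, labeled_matrix.row_class))
    )


@pytest.fixture(scope="session")
def separated_result():
    """Full pipeline on 4 well-separated classes, 200 queries per class."""
    return recovery_experiment(separated_spec(seed=0), K=1)


@pytest.fixture(scope="session")
def null_result():
    """Full pipeline on 4 statistically identical classes, 1000 queries each."""
    return recovery_experiment(null_spec(seed=0), K=1)
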