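"""End-to-end pipeline: class models -> query fits -> divergence -> report.

The three-step procedure on one similarity matrix with class annotations:

1. fit each target class's representative (Q) distribution by EM, once per
   requested mixture size K;
2. fit each query column's similarity vector against each class by
   Gaussian ML;
3. compute the query-to-class divergence table, assignments, assignment
   probability matrix, necessary-condition flags and feasibility indices.

Outputs are plain text: fitted models as JSON, tables as TSV, and a
combined ``report.json``.  Everything is a pure function of the inputs,
the configuration and the seed, so reruns are byte-identical.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .density import (
    DEFAULT_CLASS_BINS,
    DEFAULT_QUERY_BINS,
    class_density,
    write_density,
)
from .discrimination import DiscriminationReport, cumulative_divergence, discriminate
from .divergence import DivergenceTable, divergence_table
from .fitting import EMConfig, GMMParams, fit_gmm_em, save_gmm
from .simdata import (
    COMBO_RANGE,
    ClassAnnotation,
    SimilarityMatrix,
    class_block,
    read_annotation,
    read_similarity_matrix,
)
from .synthetic import fit_queries_vectorized

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    matrix_path: str
    annotations_path: str
    out_dir: str
    k_list: tuple[int, ...] = (1,)
    class_bins: int = DEFAULT_CLASS_BINS
    query_bins: int = DEFAULT_QUERY_BINS
    score_range: tuple[float, float] = COMBO_RANGE
    include_diagonal: bool = False
    direction: str = "query-to-class"
    feasibility_mode: str = "sqrt-odds"
    n_queries_per_class: int | None = None
    em_tol: float = 1e-8
    em_max_iter: int = 500
    em_restarts: int = 5
    seed: int = 0

    def em_config(self) -> EMConfig:
        return EMConfig(
            tol=self.em_tol,
            max_iter=self.em_max_iter,
            n_restarts=self.em_restarts,
            seed=self.seed,
        )

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        d.update(overrides)
        if "k_list" in d:
            d["k_list"] = tuple(int(k) for k in d["k_list"])
        if "score_range" in d:
            d["score_range"] = tuple(d["score_range"])
        return cls(**d)


@dataclass
class PipelineResult:
    """In-memory results of a run, keyed by mixture size K."""

    class_models: dict[int, dict[str, GMMParams]] = field(default_factory=dict)
    tables: dict[int, DivergenceTable] = field(default_factory=dict)
    reports: dict[int, DiscriminationReport] = field(default_factory=dict)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(
    config: RunConfig,
    matrix: SimilarityMatrix | None = None,
    annotation: ClassAnnotation | None = None,
    log=None,
) -> PipelineResult:
    """Execute steps 1-3 and write all artifacts under ``config.out_dir``.

    ``matrix``/``annotation`` may be passed in memory; otherwise they are
    read from the configured paths.  ``log`` is a writable stream (stderr
    by default).
    """
    log = log or sys.stderr
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    (out / "models").mkdir(parents=True, exist_ok=True)
    (out / "tables" / "cdf").mkdir(parents=True, exist_ok=True)

    def _log(msg: str) -> None:
        print(msg, file=log)

    _log(f"targetkl {__version__} | seed={config.seed}")
    try:
        if annotation is None:
            annotation = read_annotation(config.annotations_path)
        if matrix is None:
            matrix = read_similarity_matrix(
                config.matrix_path, annotation, score_range=config.score_range
            )
        elif set(matrix.row_class) == {""}:
            matrix = matrix.with_annotation(annotation)
    except Exception as exc:
        raise PipelineError(f"input stage failed: {exc}") from exc
    labels = list(annotation.order)
    _log(f"matrix {matrix.shape[0]}x{matrix.shape[1]}, classes: {', '.join(labels)}")

    result = PipelineResult()
    # Step 1: class Q-distributions per K
    try:
        entries = {
            lab: class_block(
                matrix, lab, include_diagonal=config.include_diagonal
            ).entries()
            for lab in labels
        }
        for lab in labels:
            dens = class_density(
                entries[lab],
                n_bins=config.class_bins,
                score_range=config.score_range,
            )
            write_density(dens, out / "tables" / f"density_{lab}.tsv")
        for k in config.k_list:
            models = {}
            for lab in labels:
                model, trace = fit_gmm_em(entries[lab], k, config.em_config())
                models[lab] = model
                save_gmm(
                    model,
                    out / "models" / f"q_{lab}_K{k}.json",
                    trace=trace,
                    extra={"class_label": lab, "n_values": int(entries[lab].size)},
                )
            result.class_models[k] = models
            _log(f"step 1 (K={k}): fitted {len(models)} class models")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"class-fitting stage failed: {exc}") from exc

    # Step 2: per-query ML Gaussians against each class
    try:
        queries = fit_queries_vectorized(
            matrix, annotation, n_queries_per_class=config.n_queries_per_class
        )
        qpayload = {
            qid: {
                "true_class": tc,
                "fits": {
                    lab: {"mu": g.mu, "sigma": g.sigma} for lab, g in fits.items()
                },
            }
            for qid, tc, fits in queries
        }
        with open(out / "models" / "queries.json", "w") as fh:
            json.dump(qpayload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        _log(f"step 2: fitted {len(queries)} queries x {len(labels)} classes")
    except Exception as exc:
        raise PipelineError(f"query-fitting stage failed: {exc}") from exc

    # Step 3: divergence tables and discrimination reports
    try:
        report_payload = {}
        for k in config.k_list:
            table = divergence_table(
                queries,
                result.class_models[k],
                class_order=labels,
                score_range=config.score_range,
                direction=config.direction,
            )
            table.write(out / "tables" / f"divergence_K{k}.tsv")
            for q_lab in labels:
                rows = [
                    i for i, tc in enumerate(table.query_classes) if tc == q_lab
                ]
                for j, t_lab in enumerate(labels):
                    vals, cdf = cumulative_divergence(table.values[rows, j])
                    np.savetxt(
                        out / "tables" / "cdf" / f"cdf_{q_lab}_{t_lab}_K{k}.tsv",
                        np.column_stack([vals, cdf]),
                        fmt="%.6f",
                        delimiter="\t",
                        header="divergence\tcumulative_density",
                    )
            rep = discriminate(table, mode=config.feasibility_mode)
            result.tables[k] = table
            result.reports[k] = rep
            report_payload[f"K={k}"] = rep.to_dict()
            _log(
                f"step 3 (K={k}): necessary={rep.necessary_ok.tolist()} "
                f"feasibility={[round(float(f), 4) for f in rep.feasibility]}"
            )
        with open(out / "report.json", "w") as fh:
            json.dump(report_payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"discrimination stage failed: {exc}") from exc

    _log(f"done in {time.perf_counter() - t0:.2f}s -> {out}")
    return result
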