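"""Exact and semantic precision/recall/F-value, holdout and k-fold CV.

Exact metrics count exact term matches: precision = N_P/N_A, recall =
N_P/N_R with N_P correctly predicted, N_A predicted, N_R real functions.

Semantic metrics credit near-misses through the ontology: each real
function scores its best cosine similarity to any predicted function
(RecallSuccess) and each predicted function its best similarity to any
real one (PrecisionSuccess); sums are normalised by the summed
self-similarities of the respective sets.  Since cosine self-similarity
is 1 the denominators equal the set sizes, but they are computed
literally so a non-cosine similarity would plug in unchanged.

The harnesses hide the annotations of held-out proteins entirely — the
influence weights and k are recomputed from the remaining (training)
annotations per fold, so hidden labels cannot leak into scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import AbstractSet, Callable, Sequence

import numpy as np

from .network import AnnotationMap, InteractionNetwork
from .ontology import Ontology
from .prediction import estimate_k, predict_cia, predict_inc, predict_nc
from .scoring import FunctionInfluence, compute_influence

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


def f_value(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@dataclass
class EvalReport:
    """Macro-averaged metrics over one or more target proteins."""

    precision: float
    recall: float
    f_value: float
    mode: str  # "exact" or "semantic"
    n_targets: int
    per_target: list[tuple[str, float, float, float]] = field(
        default_factory=list
    )
    n_skipped: int = 0  # targets with no annotated neighbour

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "precision": self.precision,
            "recall": self.recall,
            "f_value": self.f_value,
            "n_targets": self.n_targets,
            "n_skipped": self.n_skipped,
        }


def _single_report(
    mode: str, target: str, precision: float, recall: float
) -> EvalReport:
    return EvalReport(
        precision=precision,
        recall=recall,
        f_value=f_value(precision, recall),
        mode=mode,
        n_targets=1,
        per_target=[(target, precision, recall, f_value(precision, recall))],
    )


def exact_metrics(
    real: AbstractSet[str],
    predicted: AbstractSet[str],
    target: str = "",
) -> EvalReport:
    """Exact-match precision/recall/F for a single target."""
    if not real:
        raise EvaluationError("the set of real functions must be non-empty")
    n_p = len(set(real) & set(predicted))
    precision = n_p / len(predicted) if predicted else 0.0
    recall = n_p / len(real)
    return _single_report("exact", target, precision, recall)


def semantic_metrics(
    real: AbstractSet[str],
    predicted: AbstractSet[str],
    ontology: Ontology,
    closure_mode: str = "transitive",
    target: str = "",
) -> EvalReport:
    """Ontology-aware precision/recall/F for a single target."""
    if not real:
        raise EvaluationError("the set of real functions must be non-empty")
    real_list = sorted(real)
    pred_list = sorted(predicted)
    if not pred_list:
        logger.debug("empty prediction for %s: semantic metrics are 0", target)
        return _single_report("semantic", target, 0.0, 0.0)
    recall_num = sum(
        max(ontology.fsim(fo, fp, closure_mode) for fp in pred_list)
        for fo in real_list
    )
    recall_den = sum(ontology.fsim(fo, fo, closure_mode) for fo in real_list)
    precision_num = sum(
        max(ontology.fsim(fo, fp, closure_mode) for fo in real_list)
        for fp in pred_list
    )
    precision_den = sum(
        ontology.fsim(fp, fp, closure_mode) for fp in pred_list
    )
    return _single_report(
        "semantic", target, precision_num / precision_den,
        recall_num / recall_den,
    )


# A predictor takes (target, network, training annotations, ontology,
# influence, k) and returns the ordered predicted terms.
Predictor = Callable[
    [str, InteractionNetwork, AnnotationMap, Ontology, FunctionInfluence, int],
    Sequence[str],
]


def get_predictor(algorithm: str) -> Predictor:
    """Adapt a named algorithm ('cia', 'inc', 'nc') to the harness
    predictor signature."""
    if algorithm == "cia":
        return lambda p, net, ann, onto, infl, k: predict_cia(
            p, net, ann, onto, influence=infl, k=k
        ).predicted
    if algorithm == "inc":
        return lambda p, net, ann, onto, infl, k: predict_inc(
            p, net, ann, k=k
        ).predicted
    if algorithm == "nc":
        return lambda p, net, ann, onto, infl, k: predict_nc(
            p, net, ann, k=k
        ).predicted
    raise ValueError(f"unknown algorithm {algorithm!r}")


@dataclass
class PairedReport:
    """Exact and semantic reports for the same evaluation run."""

    exact: EvalReport
    semantic: EvalReport
    sample_size: int | None = None

    def to_dict(self) -> dict:
        out = {
            "exact": self.exact.to_dict(),
            "semantic": self.semantic.to_dict(),
        }
        if self.sample_size is not None:
            out["sample_size"] = self.sample_size
        return out


def _evaluate_targets(
    targets: Sequence[str],
    network: InteractionNetwork,
    train: AnnotationMap,
    full: AnnotationMap,
    ontology: Ontology,
    predictor: Predictor,
    k: int | None,
    closure_mode: str,
) -> tuple[list[tuple[str, float, float, float]],
           list[tuple[str, float, float, float]], int]:
    """Per-target exact and semantic triples; hidden-neighbourless
    targets are skipped and counted."""
    influence = compute_influence(train)
    k_eff = estimate_k(train) if k is None else k
    exact_rows: list[tuple[str, float, float, float]] = []
    sem_rows: list[tuple[str, float, float, float]] = []
    skipped = 0
    for p in targets:
        if p not in network or not any(
            train.get_terms(q) for q in network.neighbors(p)
        ):
            skipped += 1
            continue
        predicted = frozenset(
            predictor(p, network, train, ontology, influence, k_eff)
        )
        real = full[p]
        ex = exact_metrics(real, predicted, target=p)
        se = semantic_metrics(
            real, predicted, ontology, closure_mode=closure_mode, target=p
        )
        exact_rows.append(ex.per_target[0])
        sem_rows.append(se.per_target[0])
    return exact_rows, sem_rows, skipped


def _aggregate(
    mode: str,
    rows: list[tuple[str, float, float, float]],
    skipped: int,
    fold_means: list[tuple[float, float]] | None = None,
) -> EvalReport:
    if fold_means is not None and fold_means:
        precision = float(np.mean([m[0] for m in fold_means]))
        recall = float(np.mean([m[1] for m in fold_means]))
    elif rows:
        precision = float(np.mean([r[1] for r in rows]))
        recall = float(np.mean([r[2] for r in rows]))
    else:
        precision = recall = 0.0
    return EvalReport(
        precision=precision,
        recall=recall,
        f_value=f_value(precision, recall),
        mode=mode,
        n_targets=len(rows),
        per_target=rows,
        n_skipped=skipped,
    )


def cross_validate(
    network: InteractionNetwork,
    annotations: AnnotationMap,
    ontology: Ontology,
    algorithm: str | Predictor = "cia",
    folds: int = 10,
    seed: int = 0,
    k: int | None = None,
    closure_mode: str = "transitive",
) -> PairedReport:
    """k-fold cross-validation over the annotated proteins.

    Proteins are randomly partitioned by the seed; per fold the test
    proteins' annotations are hidden jointly, influence and k are
    recomputed from the training annotations, and every test protein
    with at least one annotated neighbour is predicted.  Metrics are
    macro-averaged over targets within each fold, then over folds.
    """
    proteins = sorted(annotations)
    if folds < 2:
        raise EvaluationError("need at least 2 folds")
    if folds > len(proteins):
        raise EvaluationError(
            f"{folds} folds but only {len(proteins)} annotated proteins"
        )
    predictor = (
        get_predictor(algorithm) if isinstance(algorithm, str) else algorithm
    )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(proteins))
    fold_of = np.arange(len(proteins)) % folds
    assignments: list[list[str]] = [[] for _ in range(folds)]
    for pos, idx in enumerate(order):
        assignments[fold_of[pos]].append(proteins[idx])

    exact_rows_all, sem_rows_all = [], []
    exact_fold_means, sem_fold_means = [], []
    skipped = 0
    for test in assignments:
        train = annotations.without(test)
        if len(train) == 0:
            raise EvaluationError("a fold left no training annotations")
        ex_rows, se_rows, sk = _evaluate_targets(
            sorted(test), network, train, annotations, ontology,
            predictor, k, closure_mode,
        )
        skipped += sk
        exact_rows_all.extend(ex_rows)
        sem_rows_all.extend(se_rows)
        if ex_rows:
            exact_fold_means.append(
                (float(np.mean([r[1] for r in ex_rows])),
                 float(np.mean([r[2] for r in ex_rows])))
            )
            sem_fold_means.append(
                (float(np.mean([r[1] for r in se_rows])),
                 float(np.mean([r[2] for r in se_rows])))
            )
    return PairedReport(
        exact=_aggregate("exact", exact_rows_all, skipped, exact_fold_means),
        semantic=_aggregate("semantic", sem_rows_all, skipped, sem_fold_means),
    )


def holdout_evaluate(
    network: InteractionNetwork,
    annotations: AnnotationMap,
    ontology: Ontology,
    algorithm: str | Predictor = "cia",
    sample_sizes: Sequence[int] = (20,),
    seed: int = 0,
    k: int | None = None,
    closure_mode: str = "transitive",
) -> list[PairedReport]:
    """Hold out random test sets of the given sizes and evaluate each.

    For each size, that many annotated proteins are drawn by the seed,
    their annotations hidden jointly, and metrics macro-averaged over the
    predicted targets.
    """
    proteins = sorted(annotations)
    predictor = (
        get_predictor(algorithm) if isinstance(algorithm, str) else algorithm
    )
    reports: list[PairedReport] = []
    for size in sample_sizes:
        if size < 1 or size > len(proteins):
            raise EvaluationError(
                f"sample size {size} out of range for "
                f"{len(proteins)} annotated proteins"
            )
        rng = np.random.default_rng([seed, size])
        test = [proteins[i] for i in rng.choice(len(proteins), size=size,
                                                replace=False)]
        train = annotations.without(test)
        if len(train) == 0:
            raise EvaluationError("holdout left no training annotations")
        ex_rows, se_rows, sk = _evaluate_targets(
            sorted(test), network, train, annotations, ontology,
            predictor, k, closure_mode,
        )
        reports.append(
            PairedReport(
                exact=_aggregate("exact", ex_rows, sk),
                semantic=_aggregate("semantic", se_rows, sk),
                sample_size=size,
            )
        )
    return reports


def k_sweep(
    network: InteractionNetwork,
    annotations: AnnotationMap,
    ontology: Ontology,
    algorithm: str | Predictor = "cia",
    k_values: Sequence[int] = tuple(range(1, 11)),
    sample_size: int = 20,
    seed: int = 0,
    closure_mode: str = "transitive",
) -> list[dict]:
    """Precision-recall curve points obtained by varying k.

    Returns one row per k with both exact and semantic precision/recall,
    ready for plotting.
    """
    rows = []
    for kv in k_values:
        (report,) = holdout_evaluate(
            network, annotations, ontology, algorithm=algorithm,
            sample_sizes=[sample_size], seed=seed, k=kv,
            closure_mode=closure_mode,
        )
        rows.append(
            {
                "k": kv,
                "exact_precision": report.exact.precision,
                "exact_recall": report.exact.recall,
                "semantic_precision": report.semantic.precision,
                "semantic_recall": report.semantic.recall,
            }
        )
    return rows
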