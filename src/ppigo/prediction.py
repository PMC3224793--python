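"""Iterative function predictors: CIA, plus the NC and INC baselines.

CIA (cosine iterative algorithm) alternates between two steps until the
predicted set stops changing:

1. score every candidate function f in FN(p) by summing, over annotated
   neighbours p', sim(p,p') times the neighbour's weighted semantic
   affinity for f (cosine term similarity times the IDF-style weight);
2. keep the top-k functions as the new predicted set, which redefines
   sim(p,p') for the next round.

The loop starts from the functions whose similarity-free initial scores
exceed the mean-score threshold ε.  Because the per-function influence is
fixed, only the protein similarities move between rounds; once the
predicted set repeats, the similarities — and hence every later round —
are fixed, so set stability is the convergence test.

INC is the same loop with the semantic affinity replaced by a plain
membership indicator (did the neighbour carry f?).  NC is non-iterative
neighbour counting: rank candidates by how many neighbours carry them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .network import AnnotationMap, InteractionNetwork, candidate_functions
from .ontology import Ontology
from .scoring import (
    FunctionInfluence,
    ScoreTable,
    ScoringError,
    initial_scores,
    initial_threshold,
    candidate_scores,
    protein_similarity,
)


@dataclass
class PredictionResult:
    """Outcome of predicting one target protein.

    ``trajectory`` records the predicted set after the initial selection
    and after every scoring round; ``iterations`` counts the scoring
    rounds actually run.  For a converged result the last two trajectory
    entries are identical.
    """

    target: str
    predicted: list[str]
    iterations: int
    converged: bool
    trajectory: list[frozenset[str]] = field(default_factory=list)
    initial_set: frozenset[str] = field(default_factory=frozenset)
    scores: dict[str, float] = field(default_factory=dict)

    @property
    def predicted_set(self) -> frozenset[str]:
        return frozenset(self.predicted)


def estimate_k(annotations: AnnotationMap) -> int:
    """The average number of functions per protein, rounded half-up
    (minimum 1)."""
    if len(annotations) == 0:
        raise ScoringError("cannot estimate k from an empty annotation map")
    total = sum(len(ts) for ts in annotations.values())
    mean = total / len(annotations)
    return max(1, math.floor(mean + 0.5))


def select_top_k(table: ScoreTable, k: int) -> list[str]:
    """The (at most) k highest-scoring terms; score ties break by
    ascending term id."""
    return [term for term, _ in table.ranked()[:k]]


def _empty_result(p: str) -> PredictionResult:
    return PredictionResult(
        target=p, predicted=[], iterations=0, converged=True,
        trajectory=[frozenset()], initial_set=frozenset(),
    )


def _resolve_k(
    k: int | None, annotations: AnnotationMap
) -> int:
    if k is None:
        return estimate_k(annotations)
    if k < 1:
        raise ValueError("k must be a positive integer")
    return int(k)


def _blinded_view(
    p: str, annotations: AnnotationMap
) -> tuple[AnnotationMap, FunctionInfluence]:
    """Annotations with the target hidden, plus the matching influence.

    The target's own annotations must never inform its prediction, but
    the target remains a protein *in the dataset*, so it still counts
    towards N when it carries (hidden) annotations.
    """
    had_entry = p in annotations
    visible = annotations.without([p]) if had_entry else annotations
    counts: dict[str, int] = {}
    for terms in visible.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    influence = FunctionInfluence(
        total_proteins=len(visible) + (1 if had_entry else 0),
        per_term_count=counts,
    )
    return visible, influence


def _iterate(
    p: str,
    score_fn,
    initial_table: ScoreTable,
    k: int,
    max_iterations: int,
) -> PredictionResult:
    """Shared fixed-point loop for CIA and INC.

    ``score_fn(current_set)`` returns the ScoreTable for one round.
    Stops on set equality with the previous round (converged) or when a
    previously seen non-adjacent set recurs (cycle; not converged), or at
    the iteration cap.
    """
    eps = initial_threshold(initial_table)
    initial_table.threshold = eps
    current = initial_table.above_threshold()
    if not current:
        # degenerate threshold (e.g. a single candidate, or all scores
        # equal): start from the top-k of the initial scores instead of
        # an empty set
        current = frozenset(select_top_k(initial_table, k))
    trajectory = [current]
    seen = {current}
    predicted: list[str] = []
    last_scores: dict[str, float] = dict(initial_table.scores)
    converged = False
    iterations = 0
    while iterations < max_iterations:
        table = score_fn(current)
        iterations += 1
        new_list = select_top_k(table, k)
        new_set = frozenset(new_list)
        trajectory.append(new_set)
        predicted = new_list
        last_scores = dict(table.scores)
        if new_set == current:
            converged = True
            break
        if new_set in seen:
            # revisiting an earlier state means a cycle, not a fixed point
            break
        seen.add(new_set)
        current = new_set
    return PredictionResult(
        target=p,
        predicted=predicted,
        iterations=iterations,
        converged=converged,
        trajectory=trajectory,
        initial_set=trajectory[0],
        scores=last_scores,
    )


def predict_cia(
    p: str,
    network: InteractionNetwork,
    annotations: AnnotationMap,
    ontology: Ontology,
    influence: FunctionInfluence | None = None,
    k: int | None = None,
    max_iterations: int | None = None,
    closure_mode: str = "transitive",
    closed_annotation_sets: bool = False,
) -> PredictionResult:
    """Iterative cosine-similarity prediction for one target protein.

    The target's own annotations are never consulted; ``k`` defaults to
    the dataset mean annotation count and ``max_iterations`` to k + 5
    (the loop normally stabilises within a few rounds).
    """
    visible, blinded_influence = _blinded_view(p, annotations)
    if influence is None:
        influence = blinded_influence
    annotations = visible
    k = _resolve_k(k, annotations)
    if max_iterations is None:
        max_iterations = k + 5
    annotated = [q for q in network.neighbors(p) if annotations.get_terms(q)]
    if not annotated:
        return _empty_result(p)
    table0 = initial_scores(
        p, network, annotations, ontology, influence,
        closure_mode=closure_mode,
        closed_annotation_sets=closed_annotation_sets,
    )
    if not table0:
        return _empty_result(p)

    def score_fn(current: frozenset[str]) -> ScoreTable:
        return candidate_scores(
            p, current, network, annotations, ontology, influence,
            closure_mode=closure_mode,
            closed_annotation_sets=closed_annotation_sets,
        )

    return _iterate(p, score_fn, table0, k, max_iterations)


def _frequency_table(
    p: str, network: InteractionNetwork, annotations: AnnotationMap
) -> ScoreTable:
    scores: dict[str, float] = {}
    for q in sorted(network.neighbors(p)):
        for f in sorted(annotations.get_terms(q)):
            scores[f] = scores.get(f, 0.0) + 1.0
    return ScoreTable(target=p, scores=scores)


def predict_nc(
    p: str,
    network: InteractionNetwork,
    annotations: AnnotationMap,
    k: int | None = None,
    nc_mode: str = "frequency",
) -> PredictionResult:
    """Neighbour counting: rank candidates by neighbour frequency.

    ``nc_mode='frequency'`` (default) takes the plain top-k of the
    frequency scores.  ``nc_mode='threshold'`` instead keeps the
    functions scoring strictly above the mean frequency (the same
    selection the iterative predictors use to start), truncated to k.
    """
    annotations, _ = _blinded_view(p, annotations)
    k = _resolve_k(k, annotations)
    table = _frequency_table(p, network, annotations)
    if not table:
        return _empty_result(p)
    if nc_mode == "frequency":
        predicted = select_top_k(table, k)
        chosen = frozenset(predicted)
    elif nc_mode == "threshold":
        table.threshold = initial_threshold(table)
        chosen = table.above_threshold()
        predicted = [t for t in select_top_k(table, k) if t in chosen]
    else:
        raise ValueError(f"unknown nc_mode {nc_mode!r}")
    return PredictionResult(
        target=p,
        predicted=predicted,
        iterations=0,
        converged=True,
        trajectory=[frozenset(predicted)],
        initial_set=chosen,
        scores=dict(table.scores),
    )


def predict_inc(
    p: str,
    network: InteractionNetwork,
    annotations: AnnotationMap,
    k: int | None = None,
    max_iterations: int | None = None,
) -> PredictionResult:
    """Iterative neighbour counting: the CIA loop with the weighted
    semantic affinity replaced by the membership indicator I(f ∈ F(p'))."""
    annotations, _ = _blinded_view(p, annotations)
    k = _resolve_k(k, annotations)
    if max_iterations is None:
        max_iterations = k + 5
    annotated = [q for q in network.neighbors(p) if annotations.get_terms(q)]
    if not annotated:
        return _empty_result(p)
    table0 = _frequency_table(p, network, annotations)
    if not table0:
        return _empty_result(p)

    def score_fn(current: frozenset[str]) -> ScoreTable:
        scores: dict[str, float] = {
            f: 0.0 for f in sorted(candidate_functions(network, annotations, p))
        }
        for q in sorted(network.neighbors(p)):
            fq = annotations.get_terms(q)
            if not fq:
                continue
            sim = protein_similarity(current, fq) if current else 1.0
            for f in sorted(fq):
                scores[f] += sim
        return ScoreTable(target=p, scores=scores)

    return _iterate(p, score_fn, table0, k, max_iterations)


PREDICTORS = {
    "cia": predict_cia,
    "inc": predict_inc,
    "nc": predict_nc,
}


def predict(
    algorithm: str,
    p: str,
    network: InteractionNetwork,
    annotations: AnnotationMap,
    ontology: Ontology,
    influence: FunctionInfluence | None = None,
    k: int | None = None,
    max_iterations: int | None = None,
    **kwargs,
) -> PredictionResult:
    """Dispatch to one of the named predictors with a uniform signature."""
    if algorithm == "cia":
        return predict_cia(
            p, network, annotations, ontology, influence=influence,
            k=k, max_iterations=max_iterations, **kwargs,
        )
    if algorithm == "inc":
        return predict_inc(
            p, network, annotations, k=k, max_iterations=max_iterations,
        )
    if algorithm == "nc":
        return predict_nc(p, network, annotations, k=k, **kwargs)
    raise ValueError(f"unknown algorithm {algorithm!r}")
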