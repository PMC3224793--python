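"""Candidate-function scoring: protein similarity, IDF weights, score tables.

The score of assigning a candidate function f to a target protein p sums,
over p's annotated neighbours p', the product of

* the function-overlap protein similarity between p's current predicted
  set and F(p'):   sim(p,p') = |F(p) ∩ F(p')| / max(|F(p)|, |F(p')|), and
* the local-times-global influence of the neighbour's functions:
  sum over f' in F(p') of fsim(f,f') * log(N / n_f'),

where N is the number of proteins in the dataset and n_f' the number of
proteins directly annotated with f'.  Initial scores fix sim(p,p') = 1,
and the initialisation threshold ε is the mean initial score over FN(p).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import AbstractSet, Iterable

from .network import AnnotationMap, InteractionNetwork, candidate_functions
from .ontology import Ontology

logger = logging.getLogger(__name__)


class ScoringError(ValueError):
    pass


def protein_similarity(fa: AbstractSet[str], fb: AbstractSet[str]) -> float:
    """Function-overlap similarity |fa ∩ fb| / max(|fa|, |fb|).

    Equals the normalised double sum of the exact-match indicator over the
    two annotation sets.  Symmetric; 1 iff the sets are equal; 0 iff they
    are disjoint.
    """
    if not fa or not fb:
        raise ScoringError("protein similarity requires non-empty function sets")
    return len(fa & fb) / max(len(fa), len(fb))


@dataclass
class FunctionInfluence:
    """Dataset-level term frequencies and IDF-style weights.

    weight(f) = ln(N / n_f): zero for a function carried by every protein,
    increasing as the function becomes rarer ("global influence").
    """

    total_proteins: int
    per_term_count: dict[str, int]

    def count(self, term: str) -> int:
        try:
            return self.per_term_count[term]
        except KeyError:
            raise ScoringError(f"term {term!r} annotates no protein") from None

    def weight(self, term: str) -> float:
        return math.log(self.total_proteins / self.count(term))

    def scaled(self, c: float) -> "FunctionInfluence":
        """Influence object whose weights are multiplied by ``c``."""
        return _ScaledInfluence(self.total_proteins, self.per_term_count, c)


class _ScaledInfluence(FunctionInfluence):
    def __init__(self, total, counts, factor):
        super().__init__(total, counts)
        self._factor = factor

    def weight(self, term: str) -> float:
        return self._factor * super().weight(term)


def compute_influence(annotations: AnnotationMap) -> FunctionInfluence:
    """N and n_f from the direct annotation sets of a dataset."""
    if len(annotations) == 0:
        raise ScoringError("annotation map is empty")
    counts: dict[str, int] = {}
    for terms in annotations.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    return FunctionInfluence(
        total_proteins=len(annotations), per_term_count=counts
    )


@dataclass
class ScoreTable:
    """Per-candidate-function scores for one target protein."""

    target: str
    scores: dict[str, float] = field(default_factory=dict)
    threshold: float | None = None

    def __len__(self) -> int:
        return len(self.scores)

    def __bool__(self) -> bool:
        return bool(self.scores)

    def ranked(self) -> list[tuple[str, float]]:
        """Terms by descending score, ties broken by ascending term id."""
        return sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))

    def above_threshold(self) -> frozenset[str]:
        """Terms scoring strictly above the stored threshold ε."""
        if self.threshold is None:
            raise ScoringError("no threshold set on this score table")
        return frozenset(
            t for t, s in self.scores.items() if s > self.threshold
        )

    def to_rows(self) -> list[tuple[str, int, str, float]]:
        return [
            (self.target, rank, term, score)
            for rank, (term, score) in enumerate(self.ranked(), start=1)
        ]


def _annotation_set(
    annotations: AnnotationMap,
    protein: str,
    ontology: Ontology | None,
    closed: bool,
) -> frozenset[str]:
    terms = annotations.get_terms(protein)
    if closed and ontology is not None:
        out: set[str] = set()
        for t in terms:
            out |= ontology.ancestors(t)
        return frozenset(out)
    return terms


def candidate_scores(
    p: str,
    predicted_fp: AbstractSet[str],
    network: InteractionNetwork,
    annotations: AnnotationMap,
    ontology: Ontology,
    influence: FunctionInfluence,
    closure_mode: str = "transitive",
    closed_annotation_sets: bool = False,
) -> ScoreTable:
    """Scores over FN(p) given the target's current predicted set.

    Neighbours without annotations contribute nothing and are skipped.
    An empty ``predicted_fp`` falls back to sim(p,p') = 1 for every
    neighbour (the initial-score behaviour), which keeps the iteration
    total when the threshold selects no initial function.
    """
    # iteration orders are sorted so float accumulation is identical
    # across processes regardless of string-hash randomisation
    fn = sorted(candidate_functions(network, annotations, p))
    scores: dict[str, float] = {f: 0.0 for f in fn}
    pred = frozenset(predicted_fp)
    if closed_annotation_sets and pred:
        closed_pred: set[str] = set()
        for t in pred:
            closed_pred |= ontology.ancestors(t)
        pred = frozenset(closed_pred)
    for q in sorted(network.neighbors(p)):
        fq = _annotation_set(annotations, q, ontology, closed_annotation_sets)
        if not fq:
            logger.debug("neighbour %s of %s has no annotations; skipped", q, p)
            continue
        sim = protein_similarity(pred, fq) if pred else 1.0
        if sim == 0.0:
            continue
        weighted = [(fprime, influence.weight(fprime)) for fprime in sorted(fq)]
        for f in fn:
            inner = 0.0
            for fprime, w in weighted:
                inner += ontology.fsim(f, fprime, closure_mode) * w
            scores[f] += sim * inner
    return ScoreTable(target=p, scores=scores)


def initial_scores(
    p: str,
    network: InteractionNetwork,
    annotations: AnnotationMap,
    ontology: Ontology,
    influence: FunctionInfluence,
    closure_mode: str = "transitive",
    closed_annotation_sets: bool = False,
) -> ScoreTable:
    """Scores with every protein similarity fixed to 1, plus the stored
    mean-score threshold ε."""
    table = candidate_scores(
        p,
        frozenset(),
        network,
        annotations,
        ontology,
        influence,
        closure_mode=closure_mode,
        closed_annotation_sets=closed_annotation_sets,
    )
    if table:
        table.threshold = initial_threshold(table)
    return table


def initial_threshold(table: ScoreTable) -> float:
    """ε: the arithmetic mean of the initial scores over FN(p)."""
    if not table.scores:
        raise ScoringError("cannot take the threshold of an empty score table")
    return sum(table.scores.values()) / len(table.scores)


def scores_to_tsv(tables: Iterable[ScoreTable], path) -> None:
    """Write ranked scores as TSV: protein, term, score, rank."""
    with open(path, "w") as fh:
        fh.write("protein\tterm\tscore\trank\n")
        for table in tables:
            for protein, rank, term, score in table.to_rows():
                fh.write(f"{protein}\t{term}\t{score:.10g}\t{rank}\n")
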