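"""Independent brute-force reference implementations used by the tests.

Everything here is written as a literal transcription of the defining
formulas — dense vectors, explicit nested loops, no sharing of code with
the package under test — so agreement is meaningful.  Accumulation follows the same sorted
iteration order the scoring definitions prescribe, so float sums are
bit-identical when the formulas agree.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------- ontology

def dense_ancestor_vector(parents_of: dict[str, set[str]], term: str,
                          order: list[str], mode: str = "transitive"):
    """0/1 numpy vector over ``order`` for term + its ancestors."""
    if mode == "transitive":
        members = {term}
        frontier = [term]
        while frontier:
            cur = frontier.pop()
            for par in parents_of[cur]:
                if par not in members:
                    members.add(par)
                    frontier.append(par)
    else:  # parents_only
        members = {term} | set(parents_of[term])
    vec = np.zeros(len(order))
    for t in members:
        vec[order.index(t)] = 1.0
    return vec


def cosine(v1, v2) -> float:
    denom = math.sqrt(float(np.dot(v1, v1)) * float(np.dot(v2, v2)))
    return float(np.dot(v1, v2)) / denom


def fsim_oracle(parents_of, f, fprime, order, mode="transitive") -> float:
    return cosine(
        dense_ancestor_vector(parents_of, f, order, mode),
        dense_ancestor_vector(parents_of, fprime, order, mode),
    )


def reachable(parents_of: dict[str, set[str]], term: str) -> set[str]:
    """Brute-force reachability over parent links, term excluded."""
    out: set[str] = set()
    frontier = list(parents_of[term])
    while frontier:
        cur = frontier.pop()
        if cur not in out:
            out.add(cur)
            frontier.extend(parents_of[cur])
    return out


def has_cycle(parents_of: dict[str, set[str]]) -> bool:
    """Depth-first search cycle check on the parent relation."""
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {t: WHITE for t in parents_of}
    def visit(t):
        colour[t] = GREY
        for par in parents_of[t]:
            if colour[par] == GREY:
                return True
            if colour[par] == WHITE and visit(par):
                return True
        colour[t] = BLACK
        return False
    return any(colour[t] == WHITE and visit(t) for t in parents_of)


# ----------------------------------------------------------------- scoring

def sim_oracle(fa: set[str], fb: set[str]) -> float:
    """Double loop over the exact-match indicator."""
    total = 0
    for f in fa:
        for fp in fb:
            if f == fp:
                total += 1
    return total / max(len(fa), len(fb))


def weight_oracle(n_total: int, n_f: int) -> float:
    return math.log(n_total / n_f)


def fn_of(neighbors_of, annotations, p) -> set[str]:
    out: set[str] = set()
    for q in neighbors_of[p]:
        out |= set(annotations.get(q, set()))
    return out


def score_oracle(p, predicted_fp, neighbors_of, annotations, parents_of,
                 order, n_total, counts, mode="transitive"):
    """Literal nested-loop evaluation of the candidate-function score:
    sum over neighbours of sim x (sum over their functions of
    fsim x log(N/n_f'))."""
    scores = {}
    for f in sorted(fn_of(neighbors_of, annotations, p)):
        total = 0.0
        for q in sorted(neighbors_of[p]):
            fq = set(annotations.get(q, set()))
            if not fq:
                continue
            if predicted_fp:
                s = sim_oracle(set(predicted_fp), fq)
            else:
                s = 1.0
            inner = 0.0
            for fprime in sorted(fq):
                inner += (
                    fsim_oracle(parents_of, f, fprime, order, mode)
                    * weight_oracle(n_total, counts[fprime])
                )
            total += s * inner
        scores[f] = total
    return scores


def initial_score_oracle(p, neighbors_of, annotations, parents_of, order,
                         n_total, counts, mode="transitive"):
    """Scores with every protein similarity forced to 1."""
    scores = {}
    for f in sorted(fn_of(neighbors_of, annotations, p)):
        total = 0.0
        for q in sorted(neighbors_of[p]):
            for fprime in sorted(annotations.get(q, set())):
                total += (
                    fsim_oracle(parents_of, f, fprime, order, mode)
                    * weight_oracle(n_total, counts[fprime])
                )
        scores[f] = total
    return scores


def topk_oracle(scores: dict[str, float], k: int) -> list[str]:
    ordered = sorted(scores, key=lambda t: (-scores[t], t))
    return ordered[:k]


# -------------------------------------------------------------- prediction

def cia_oracle(p, neighbors_of, annotations, parents_of, order, n_total,
               counts, k, max_iterations, mode="transitive"):
    """Step-by-step transcription of the iterative procedure.

    Returns (predicted list, trajectory of sets, iterations, converged).
    """
    init = initial_score_oracle(
        p, neighbors_of, annotations, parents_of, order, n_total, counts,
        mode,
    )
    if not init:
        return [], [frozenset()], 0, True
    eps = sum(init.values()) / len(init)
    current = frozenset(f for f, s in init.items() if s > eps)
    if not current:
        current = frozenset(topk_oracle(init, k))
    trajectory = [current]
    seen = {current}
    predicted: list[str] = []
    converged = False
    iterations = 0
    while iterations < max_iterations:
        scores = score_oracle(
            p, current, neighbors_of, annotations, parents_of, order,
            n_total, counts, mode,
        )
        iterations += 1
        predicted = topk_oracle(scores, k)
        new = frozenset(predicted)
        trajectory.append(new)
        if new == current:
            converged = True
            break
        if new in seen:
            break
        seen.add(new)
        current = new
    return predicted, trajectory, iterations, converged


def inc_score_oracle(p, predicted_fp, neighbors_of, annotations):
    """Membership-indicator scores: sum over neighbours of sim x I."""
    scores = {}
    for f in sorted(fn_of(neighbors_of, annotations, p)):
        total = 0.0
        for q in sorted(neighbors_of[p]):
            fq = set(annotations.get(q, set()))
            if not fq:
                continue
            s = sim_oracle(set(predicted_fp), fq) if predicted_fp else 1.0
            indicator = 1.0 if f in fq else 0.0
            total += s * indicator
        scores[f] = total
    return scores


def nc_score_oracle(p, neighbors_of, annotations):
    """Frequency: number of neighbours carrying each candidate."""
    scores = {}
    for f in sorted(fn_of(neighbors_of, annotations, p)):
        scores[f] = float(
            sum(1 for q in neighbors_of[p]
                if f in annotations.get(q, set()))
        )
    return scores


def inc_oracle(p, neighbors_of, annotations, k, max_iterations):
    init = nc_score_oracle(p, neighbors_of, annotations)
    if not init:
        return [], [frozenset()], 0, True
    eps = sum(init.values()) / len(init)
    current = frozenset(f for f, s in init.items() if s > eps)
    if not current:
        current = frozenset(topk_oracle(init, k))
    trajectory = [current]
    seen = {current}
    predicted: list[str] = []
    converged = False
    iterations = 0
    while iterations < max_iterations:
        scores = inc_score_oracle(p, current, neighbors_of, annotations)
        iterations += 1
        predicted = topk_oracle(scores, k)
        new = frozenset(predicted)
        trajectory.append(new)
        if new == current:
            converged = True
            break
        if new in seen:
            break
        seen.add(new)
        current = new
    return predicted, trajectory, iterations, converged


# -------------------------------------------------------------- evaluation

def semantic_metrics_oracle(real, predicted, parents_of, order,
                            mode="transitive"):
    """Nested-max transcription of the semantic recall/precision."""
    real = sorted(real)
    predicted = sorted(predicted)
    if not predicted:
        return 0.0, 0.0
    recall_num = 0.0
    for fo in real:
        recall_num += max(
            fsim_oracle(parents_of, fo, fp, order, mode) for fp in predicted
        )
    recall_den = sum(
        fsim_oracle(parents_of, fo, fo, order, mode) for fo in real
    )
    prec_num = 0.0
    for fp in predicted:
        prec_num += max(
            fsim_oracle(parents_of, fo, fp, order, mode) for fo in real
        )
    prec_den = sum(
        fsim_oracle(parents_of, fp, fp, order, mode) for fp in predicted
    )
    return prec_num / prec_den, recall_num / recall_den


# ------------------------------------------------------- random instances

def random_instance(rng, max_proteins=10, max_terms=20):
    """A small random DAG + annotated network for fuzzing.

    Returns (parents_of, order, neighbors_of, annotations).  Every
    protein gets at least one term; the network may contain isolated
    proteins but no self loops.
    """
    n_terms = int(rng.integers(2, max_terms + 1))
    order = [f"T{i:03d}" for i in range(n_terms)]
    parents_of: dict[str, set[str]] = {}
    for i, t in enumerate(order):
        if i == 0 or rng.random() < 0.2:
            parents_of[t] = set()
        else:
            n_par = int(rng.integers(1, min(i, 3) + 1))
            chosen = rng.choice(i, size=n_par, replace=False)
            parents_of[t] = {order[int(j)] for j in chosen}
    n_prot = int(rng.integers(2, max_proteins + 1))
    proteins = [f"P{i:02d}" for i in range(n_prot)]
    annotations = {}
    for p in proteins:
        n_ann = int(rng.integers(1, min(n_terms, 5) + 1))
        chosen = rng.choice(n_terms, size=n_ann, replace=False)
        annotations[p] = {order[int(j)] for j in chosen}
    neighbors_of = {p: set() for p in proteins}
    for i in range(n_prot):
        for j in range(i + 1, n_prot):
            if rng.random() < 0.4:
                neighbors_of[proteins[i]].add(proteins[j])
                neighbors_of[proteins[j]].add(proteins[i])
    return parents_of, order, neighbors_of, annotations
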