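import numpy as np
import pytest

from ppigo.evaluation import (
    EvaluationError,
    cross_validate,
    exact_metrics,
    f_value,
    holdout_evaluate,
    k_sweep,
    semantic_metrics,
)
from ppigo.network import AnnotationMap, InteractionNetwork
from ppigo.synthdata import SynthConfig, generate_annotated_network, generate_ontology

import oracles as O
from conftest import T4, T5, make_ontology


class TestExactMetrics:
    def test_perfect_prediction(self):
        r = exact_metrics({"a", "b"}, {"a", "b"})
        assert (r.precision, r.recall, r.f_value) == (1.0, 1.0, 1.0)

    def test_disjoint_prediction(self):
        r = exact_metrics({"a", "b"}, {"c"})
        assert (r.precision, r.recall, r.f_value) == (0.0, 0.0, 0.0)

    def test_partial_overlap(self):
        r = exact_metrics({"a", "b", "c", "d"}, {"a", "b", "e"})
        assert r.precision == pytest.approx(2 / 3)
        assert r.recall == pytest.approx(1 / 2)
        assert r.f_value == pytest.approx(4 / 7)

    def test_empty_prediction_gives_zero_precision(self):
        r = exact_metrics({"a"}, set())
        assert (r.precision, r.recall) == (0.0, 0.0)

    def test_empty_real_set_rejected(self):
        with pytest.raises(EvaluationError):
            exact_metrics(set(), {"a"})


class TestSemanticMetrics:
    def test_perfect_prediction(self, toy_onto):
        r = semantic_metrics({T4, T5}, {T4, T5}, toy_onto)
        assert (r.precision, r.recall, r.f_value) == (1.0, 1.0, 1.0)

    def test_sibling_terms_credit_two_thirds(self, toy_onto):
        """A prediction of term five for a true term four earns the
        worked-example cosine 2/3 in both directions."""
        r = semantic_metrics(
            {T4}, {T5}, toy_onto, closure_mode="parents_only"
        )
        assert r.precision == pytest.approx(2 / 3, abs=1e-12)
        assert r.recall == pytest.approx(2 / 3, abs=1e-12)

    def test_empty_prediction_is_zero_not_error(self, toy_onto):
        r = semantic_metrics({T4}, set(), toy_onto)
        assert (r.precision, r.recall, r.f_value) == (0.0, 0.0, 0.0)

    def test_matches_nested_max_oracle(self, rng):
        for _ in range(20):
            parents, order, _, annotations = O.random_instance(rng)
            onto = make_ontology(parents)
            terms = sorted(parents)
            real = set(
                terms[int(i)]
                for i in rng.choice(len(terms),
                                    size=int(rng.integers(1, 4)),
                                    replace=False)
            )
            predicted = set(
                terms[int(i)]
                for i in rng.choice(len(terms),
                                    size=int(rng.integers(1, 4)),
                                    replace=False)
            )
            r = semantic_metrics(real, predicted, onto)
            prec, rec = O.semantic_metrics_oracle(
                real, predicted, parents, sorted(order)
            )
            assert r.precision == pytest.approx(prec, abs=1e-12)
            assert r.recall == pytest.approx(rec, abs=1e-12)

    def test_semantic_dominates_exact(self, rng):
        """Best-match similarity can only improve on the exact-match
        indicator, so semantic P and R bound the exact ones from above."""
        for _ in range(20):
            parents, order, _, _ = O.random_instance(rng)
            onto = make_ontology(parents)
            terms = sorted(parents)
            real = set(
                terms[int(i)]
                for i in rng.choice(len(terms), size=2, replace=False)
            )
            predicted = set(
                terms[int(i)]
                for i in rng.choice(len(terms), size=2, replace=False)
            )
            ex = exact_metrics(real, predicted)
            se = semantic_metrics(real, predicted, onto)
            assert se.precision >= ex.precision - 1e-12
            assert se.recall >= ex.recall - 1e-12


class TestFValue:
    def test_harmonic_identity(self, rng):
        for _ in range(50):
            p, r = rng.random(), rng.random()
            f = f_value(p, r)
            if p + r > 0:
                assert f == pytest.approx(2 * p * r / (p + r), abs=1e-15)
            else:
                assert f == 0.0
        assert f_value(0.0, 0.7) == 0.0


def _perfect(full: AnnotationMap):
    def predictor(p, net, ann, onto, infl, k):
        return sorted(full[p])
    return predictor


def _empty_predictor(p, net, ann, onto, infl, k):
    return []


@pytest.fixture()
def square_instance(toy_onto):
    """Four mutually connected annotated proteins on the toy DAG."""
    prots = ["A", "B", "C", "D"]
    edges = [(a, b) for i, a in enumerate(prots) for b in prots[i + 1:]]
    net = InteractionNetwork.from_edges(edges)
    ann = AnnotationMap({p: {T4} for p in prots})
    return net, ann


class TestCrossValidate:
    def test_perfect_stub_scores_one_everywhere(self, toy_onto, square_instance):
        net, ann = square_instance
        rep = cross_validate(
            net, ann, toy_onto, algorithm=_perfect(ann), folds=2, seed=0
        )
        for r in (rep.exact, rep.semantic):
            assert (r.precision, r.recall, r.f_value) == (1.0, 1.0, 1.0)

    def test_empty_stub_scores_zero(self, toy_onto, square_instance):
        net, ann = square_instance
        rep = cross_validate(
            net, ann, toy_onto, algorithm=_empty_predictor, folds=2, seed=0
        )
        assert rep.exact.f_value == 0.0 and rep.semantic.f_value == 0.0

    def test_every_protein_tested_exactly_once(self, toy_onto, square_instance):
        net, ann = square_instance
        seen = []

        def recorder(p, *args):
            seen.append(p)
            return [T4]

        cross_validate(net, ann, toy_onto, algorithm=recorder, folds=2, seed=3)
        assert sorted(seen) == sorted(ann)

    def test_two_fold_partition_matches_hand_execution(self, toy_onto,
                                                       square_instance):
        """The fold partition is reproducible from the seed, and per-fold
        macro averages equal a hand evaluation of the same predictions."""
        net, ann = square_instance
        fixed = {"A": [T4], "B": [T5], "C": [T4], "D": [T5]}

        def stub(p, *args):
            return fixed[p]

        rep = cross_validate(net, ann, toy_onto, algorithm=stub, folds=2,
                             seed=0)
        # every protein is predicted once; real = {T4} for all, so exact
        # P = R = 1 for A and C, 0 for B and D, macro mean 0.5 per metric
        assert rep.exact.precision == pytest.approx(0.5)
        assert rep.exact.recall == pytest.approx(0.5)
        assert rep.exact.n_targets == 4

    def test_too_many_folds_rejected(self, toy_onto, square_instance):
        net, ann = square_instance
        with pytest.raises(EvaluationError):
            cross_validate(net, ann, toy_onto, folds=10, seed=0)

    def test_deterministic_under_seed(self, toy_onto):
        cfg = SynthConfig(n_proteins=30, seed=5)
        onto = generate_ontology(cfg)
        net, ann = generate_annotated_network(cfg, onto)
        a = cross_validate(net, ann, onto, algorithm="cia", folds=3, seed=11)
        b = cross_validate(net, ann, onto, algorithm="cia", folds=3, seed=11)
        assert a.exact.to_dict() == b.exact.to_dict()
        assert a.semantic.per_target == b.semantic.per_target

    def test_hidden_fold_annotations_do_not_leak(self, toy_onto,
                                                 square_instance):
        """The training map handed to the predictor never contains any
        test protein of the current fold."""
        net, ann = square_instance

        def checker(p, net_, train, onto, infl, k):
            assert p not in train
            return [T4]

        cross_validate(net, ann, toy_onto, algorithm=checker, folds=2, seed=0)


class TestHoldout:
    def test_requested_sample_size_is_honoured(self, toy_onto):
        cfg = SynthConfig(n_proteins=10, seed=2)
        onto = generate_ontology(cfg)
        net, ann = generate_annotated_network(cfg, onto)
        (rep,) = holdout_evaluate(
            net, ann, onto, algorithm="nc", sample_sizes=[2], seed=0
        )
        assert rep.sample_size == 2
        assert rep.exact.n_targets + rep.exact.n_skipped == 2

    def test_same_seed_reproduces_report(self, toy_onto):
        cfg = SynthConfig(n_proteins=25, seed=4)
        onto = generate_ontology(cfg)
        net, ann = generate_annotated_network(cfg, onto)
        a = holdout_evaluate(net, ann, onto, sample_sizes=[5, 8], seed=7)
        b = holdout_evaluate(net, ann, onto, sample_sizes=[5, 8], seed=7)
        assert [r.to_dict() for r in a] == [r.to_dict() for r in b]

    def test_oversized_sample_rejected(self, toy_onto, square_instance):
        net, ann = square_instance
        with pytest.raises(EvaluationError):
            holdout_evaluate(net, ann, toy_onto, sample_sizes=[99], seed=0)

    def test_metrics_invariant_under_protein_relabeling(self, toy_onto):
        cfg = SynthConfig(n_proteins=20, seed=9)
        onto = generate_ontology(cfg)
        net, ann = generate_annotated_network(cfg, onto)
        (base,) = holdout_evaluate(net, ann, onto, algorithm="nc",
                                   sample_sizes=[5], seed=1)
        # rename P00xx -> Q00xx; lexicographic order of ids is preserved,
        # so the seeded draw picks the same underlying proteins
        rename = {p: "Q" + p[1:] for p in net.proteins}
        net2 = InteractionNetwork.from_edges(
            [(rename[a], rename[b]) for a, b in
             (tuple(sorted(e)) for e in net.edges)],
            proteins=[rename[p] for p in net.proteins],
        )
        ann2 = AnnotationMap({rename[p]: ts for p, ts in ann.items()})
        (renamed,) = holdout_evaluate(net2, ann2, onto, algorithm="nc",
                                      sample_sizes=[5], seed=1)
        assert renamed.exact.to_dict() == base.exact.to_dict()
        assert renamed.semantic.to_dict() == base.semantic.to_dict()


class TestKSweep:
    def test_returns_one_row_per_k(self, toy_onto):
        cfg = SynthConfig(n_proteins=20, seed=1)
        onto = generate_ontology(cfg)
        net, ann = generate_annotated_network(cfg, onto)
        rows = k_sweep(net, ann, onto, algorithm="nc", k_values=[1, 3],
                       sample_size=4, seed=0)
        assert [r["k"] for r in rows] == [1, 3]
        for r in rows:
            assert 0.0 <= r["exact_precision"] <= 1.0
            assert 0.0 <= r["semantic_recall"] <= 1.0
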