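import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kgddi.evalx import (
    all_metrics,
    aupr,
    auroc,
    confusion,
    ConfusionCounts,
    EvalError,
    evaluate,
    kfold_plan,
    point_metrics,
    pwcv_plan,
)


class TestConfusion:
    def test_basic_counts(self):
        c = confusion([1, 0], [0.9, 0.1], 0.5)
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)

    def test_all_missed_positives(self):
        c = confusion([1] * 5, [0.1] * 5, 0.5)
        assert c.fn == 5 and c.tp == 0

    def test_zero_threshold_everything_positive(self):
        c = confusion([1, 0, 0], [0.0, 0.2, 0.9], 0.0)
        assert c.tn == 0 and c.fn == 0
        assert c.tp + c.fp == 3

    def test_empty_fatal(self):
        with pytest.raises(EvalError):
            confusion([], [], 0.5)


class TestPointMetrics:
    def test_perfect_classifier(self):
        m = point_metrics(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        assert all(m[k] == 1.0 for k in ("acc", "sen", "spe", "pre", "f1", "mcc"))

    def test_chance_counts(self):
        m = point_metrics(ConfusionCounts(tp=5, fp=5, tn=5, fn=5))
        assert m["mcc"] == 0.0
        assert m["acc"] == 0.5

    def test_hand_computed_mcc(self):
        m = point_metrics(ConfusionCounts(tp=4, fp=1, tn=3, fn=2))
        assert m["mcc"] == pytest.approx(10 / math.sqrt(600))

    def test_undefined_ratio_flagged_as_nan(self):
        m = point_metrics(ConfusionCounts(tp=0, fp=0, tn=3, fn=2))
        assert math.isnan(m["pre"])

    def test_mcc_antisymmetric_under_prediction_flip(self):
        c = ConfusionCounts(tp=4, fp=1, tn=3, fn=2)
        flipped = ConfusionCounts(tp=c.fn, fp=c.tn, tn=c.fp, fn=c.tp)
        assert point_metrics(flipped)["mcc"] == pytest.approx(-point_metrics(c)["mcc"])


def brute_force_auroc(labels, scores):
    """Concordant-pair counting with half credit for ties."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRankingMetrics:
    def test_perfect_separation(self):
        assert auroc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert aupr([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_constant_scores_chance(self):
        assert auroc([0, 1, 0, 1], [0.5] * 4) == 0.5

    def test_hand_value(self):
        assert auroc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1]) == pytest.approx(0.75)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 1), min_size=2, max_size=12),
        st.integers(0, 2**31 - 1),
    )
    def test_matches_exhaustive_concordance_oracle(self, labels, seed):
        if len(set(labels)) < 2:
            labels = labels[:-1] + [1 - labels[-1]]
        rs = np.random.default_rng(seed)
        scores = rs.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=len(labels))
        assert auroc(labels, scores) == pytest.approx(brute_force_auroc(labels, scores))

    def test_single_class_fatal(self):
        with pytest.raises(EvalError):
            auroc([1, 1], [0.5, 0.6])


class TestKfoldPlan:
    def test_stratified_partition(self):
        labels = np.array([1] * 50 + [0] * 50)
        plan = kfold_plan(labels, k=10, repeats=1, seed=0)
        assert len(plan.folds) == 10
        seen = []
        for tr, te in plan.folds:
            assert len(te) == 10
            assert labels[te].sum() == 5  # stratification
            assert set(tr) | set(te) == set(range(100))
            seen.extend(te)
        assert sorted(seen) == list(range(100))  # disjoint exhaustive

    def test_repeats_and_determinism(self):
        labels = np.array([1] * 30 + [0] * 30)
        p1 = kfold_plan(labels, k=3, repeats=2, seed=4)
        p2 = kfold_plan(labels, k=3, repeats=2, seed=4)
        assert len(p1.folds) == 6
        for (a, b), (c, d) in zip(p1.folds, p2.folds):
            assert np.array_equal(a, c) and np.array_equal(b, d)

    def test_small_class_fatal(self):
        with pytest.raises(EvalError):
            kfold_plan(np.array([1] * 3 + [0] * 50), k=10)


class TestPwcvPlan:
    def test_two_fold_toy(self):
        pairs = [("a", "b"), ("c", "d")]
        # seed chosen so the random drug partition is {a,b} | {c,d}
        plan = pwcv_plan(pairs, k=2, seed=5)
        for tr, te in plan.folds:
            assert len(tr) == 1 and len(te) == 1
            assert tr[0] != te[0]

    def test_straddling_pair_excluded(self):
        pairs = [("a", "b"), ("c", "d"), ("a", "c")]
        plan = pwcv_plan(pairs, k=2, seed=5)
        assert sum(plan.discarded) >= 1
        for (tr, te), disc in zip(plan.folds, plan.discarded):
            assert len(tr) + len(te) + disc == len(pairs)

    def test_drug_sets_disjoint_in_every_fold(self, small_world):
        name2id = small_world.kg.name_to_id()
        pairs = [
            (name2id[a], name2id[b]) for (a, b), lab, _ in small_world.pairs if lab == 1
        ]
        plan = pwcv_plan(pairs, k=4, seed=1)
        for tr, te in plan.folds:
            tr_drugs = {d for i in tr for d in pairs[i]}
            te_drugs = {d for i in te for d in pairs[i]}
            assert not (tr_drugs & te_drugs)

    def test_one_unseen_mode_keeps_straddlers_in_test(self):
        pairs = [("a", "b"), ("c", "d"), ("a", "c")]
        plan = pwcv_plan(pairs, k=2, seed=5, mode="one-unseen")
        for tr, te in plan.folds:
            assert len(tr) + len(te) == len(pairs)

    def test_too_few_drugs_fatal(self):
        with pytest.raises(EvalError):
            pwcv_plan([("a", "b")], k=2)


class TestEvaluate:
    def setup_inputs(self):
        rs = np.random.default_rng(0)
        labels = np.array([1] * 30 + [0] * 30)
        pairs = [(i, i + 100) for i in range(60)]
        return pairs, labels, rs

    def test_oracle_scorer_all_metrics_one(self):
        pairs, labels, _ = self.setup_inputs()
        plan = kfold_plan(labels, k=3, repeats=2, seed=0)
        report = evaluate(lambda tr, te: labels[te].astype(float), plan, pairs, labels)
        for m in ("acc", "sen", "spe", "pre", "f1", "mcc", "auroc", "aupr"):
            assert report.mean[m] == pytest.approx(1.0)
            assert report.rsd[m] == pytest.approx(0.0)

    def test_constant_scorer_chance_auroc(self):
        pairs, labels, _ = self.setup_inputs()
        plan = kfold_plan(labels, k=3, repeats=1, seed=0)
        report = evaluate(lambda tr, te: np.full(len(te), 0.5), plan, pairs, labels)
        assert report.mean["auroc"] == pytest.approx(0.5)

    def test_failure_annotated_with_fold(self):
        pairs, labels, _ = self.setup_inputs()
        plan = kfold_plan(labels, k=3, repeats=1, seed=0)

        def bad(tr, te):
            raise RuntimeError("boom")

        with pytest.raises(EvalError, match="fold 0"):
            evaluate(bad, plan, pairs, labels)

    def test_rsd_definition(self):
        # two folds with AUROC 1.0 and a known lower value -> RSD = 100*sd/mean
        pairs, labels, _ = self.setup_inputs()
        plan = kfold_plan(labels, k=2, repeats=1, seed=0)
        flip = {"i": 0}

        def scorer(tr, te):
            flip["i"] += 1
            if flip["i"] == 1:
                return labels[te].astype(float)
            return 1.0 - labels[te]  # perfectly wrong

        report = evaluate(scorer, plan, pairs, labels)
        vals = [f["auroc"] for f in report.per_fold]
        mu, sd = np.mean(vals), np.std(vals, ddof=1)
        assert report.rsd["auroc"] == pytest.approx(100 * sd / mu)


def test_all_metrics_bundle_keys():
    m = all_metrics([1, 0, 1, 0], [0.9, 0.2, 0.7, 0.4])
    assert set(m) == {"acc", "sen", "spe", "pre", "f1", "mcc", "auroc", "aupr"}
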