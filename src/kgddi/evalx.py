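"""Evaluation harness: confusion metrics, ranking metrics, repeated
stratified 10-fold CV, and pairwise-disjoint (cold-start) CV.

The pairwise-disjoint split partitions *drugs* (not pairs) into folds: a
fold's test pairs have both drugs inside the held-out drug set and its train
pairs have both drugs outside it, so no test drug is ever seen in training —
the cold-start scenario under which DDI models degrade sharply relative to
traditional pair-level k-fold CV. Aggregates are reported as mean and RSD(%)
= 100 * sd / mean across repeats, the field's table convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

METRIC_NAMES = ("acc", "sen", "spe", "pre", "f1", "mcc", "auroc", "aupr")


class EvalError(ValueError):
    pass


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class SplitPlan:
    mode: str  # "kfold" | "pwcv"
    folds: list  # list of (train_indices, test_indices) per repeat, flattened
    repeats: int
    seed: int
    fold_repeat: list = field(default_factory=list)  # repeat index per fold
    discarded: list = field(default_factory=list)  # pwcv straddling-pair counts


@dataclass
class MetricReport:
    per_fold: list  # list of dicts metric -> value (NaN where undefined)
    mode: str
    mean: dict = field(default_factory=dict)
    rsd: dict = field(default_factory=dict)
    n_undefined: dict = field(default_factory=dict)

    def __post_init__(self):
        for m in METRIC_NAMES:
            vals = np.array([f[m] for f in self.per_fold], dtype=float)
            ok = vals[np.isfinite(vals)]
            self.n_undefined[m] = int(len(vals) - len(ok))
            if len(ok) == 0:
                self.mean[m], self.rsd[m] = math.nan, math.nan
                continue
            mu = float(ok.mean())
            sd = float(ok.std(ddof=1)) if len(ok) > 1 else 0.0
            self.mean[m] = mu
            self.rsd[m] = 100.0 * sd / mu if mu != 0 else math.nan


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Counts at the rule score >= threshold -> predicted positive."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0:
        raise EvalError("empty input")
    if labels.shape != scores.shape:
        raise EvalError("labels and scores must have equal length")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int((pred & pos).sum()),
        fp=int((pred & ~pos).sum()),
        tn=int((~pred & ~pos).sum()),
        fn=int((~pred & pos).sum()),
    )


def point_metrics(c: ConfusionCounts) -> dict:
    """acc/sen/spe/pre/f1/mcc from counts; undefined ratios come back as NaN."""

    def ratio(num, den):
        return num / den if den > 0 else math.nan

    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    acc = ratio(tp + tn, c.total)
    sen = ratio(tp, tp + fn)
    spe = ratio(tn, tn + fp)
    pre = ratio(tp, tp + fp)
    f1 = ratio(2 * tp, 2 * tp + fp + fn)
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else math.nan
    return {"acc": acc, "sen": sen, "spe": spe, "pre": pre, "f1": f1, "mcc": mcc}


def auroc(labels, scores) -> float:
    """Rank-based AUROC (midranks for ties)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise EvalError("AUROC needs both classes present")
    return float(roc_auc_score(labels, scores))


def aupr(labels, scores) -> float:
    """Area under the precision-recall curve by step integration."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise EvalError("AUPR needs both classes present")
    return float(average_precision_score(labels, scores))


def all_metrics(labels, scores, threshold: float = 0.5) -> dict:
    out = point_metrics(confusion(labels, scores, threshold))
    out["auroc"] = auroc(labels, scores)
    out["aupr"] = aupr(labels, scores)
    return out


def kfold_plan(labels, k: int = 10, repeats: int = 10, seed: int = 0) -> SplitPlan:
    """Repeated stratified k-fold over pair indices."""
    labels = np.asarray(labels)
    for cls in np.unique(labels):
        if (labels == cls).sum() < k:
            raise EvalError(f"class {cls} has fewer than k={k} pairs")
    folds, fold_repeat = [], []
    idx = np.arange(len(labels))
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        for tr, te in skf.split(idx, labels):
            folds.append((idx[tr], idx[te]))
            fold_repeat.append(rep)
    return SplitPlan("kfold", folds, repeats, seed, fold_repeat)


def pwcv_plan(pairs, k: int = 10, seed: int = 0, mode: str = "both-unseen") -> SplitPlan:
    """Cold-start plan: partition drugs into k folds.

    Default ``both-unseen``: a fold's test pairs have both drugs in the
    held-out drug set; train pairs have both outside; straddling pairs are
    discarded for that fold (counts recorded). ``one-unseen``: test pairs
    have at least one held-out drug.
    """
    if mode not in ("both-unseen", "one-unseen"):
        raise EvalError(f"unknown pwcv mode {mode!r}")
    drugs = sorted({d for p in pairs for d in p})
    if len(drugs) < 2 * k:
        raise EvalError(f"need at least {2 * k} distinct drugs for {k} drug-folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(drugs))
    assignment = {drugs[j]: i % k for i, j in enumerate(order)}
    folds, discarded = [], []
    for f in range(k):
        train, test, straddle = [], [], 0
        for i, (a, b) in enumerate(pairs):
            held_a, held_b = assignment[a] == f, assignment[b] == f
            if mode == "both-unseen":
                if held_a and held_b:
                    test.append(i)
                elif not held_a and not held_b:
                    train.append(i)
                else:
                    straddle += 1
            else:
                if held_a or held_b:
                    test.append(i)
                else:
                    train.append(i)
        if not test:
            raise EvalError(f"drug-fold {f} has no test pairs; use a smaller k")
        # runtime guarantee, not just a test: cold-start folds never share drugs
        tr_drugs = {d for i in train for d in pairs[i]}
        te_drugs = {d for i in test for d in pairs[i]}
        if mode == "both-unseen":
            assert not (tr_drugs & te_drugs), "pwcv fold leaked drugs between splits"
        folds.append((np.array(train), np.array(test)))
        discarded.append(straddle)
    return SplitPlan("pwcv", folds, 1, seed, [0] * len(folds), discarded)


def evaluate(trainer, plan: SplitPlan, pairs, labels, threshold: float = 0.5) -> MetricReport:
    """Train per fold from scratch and aggregate metrics over repeats.

    ``trainer(train_idx, test_idx) -> scores over test_idx`` encapsulates the
    whole modeling path (embedding learning included) so nothing fit on test
    pairs leaks into training.
    """
    labels = np.asarray(labels)
    per_fold = []
    for fold_id, (tr, te) in enumerate(plan.folds):
        try:
            scores = np.asarray(trainer(np.asarray(tr), np.asarray(te)), dtype=float)
        except Exception as exc:  # noqa: BLE001 - annotate with fold id per contract
            raise EvalError(f"training failed in fold {fold_id}: {exc}") from exc
        fold_labels = labels[np.asarray(te)]
        m = point_metrics(confusion(fold_labels, scores, threshold))
        if len(np.unique(fold_labels)) < 2:
            m["auroc"], m["aupr"] = math.nan, math.nan
        else:
            m["auroc"] = auroc(fold_labels, scores)
            m["aupr"] = aupr(fold_labels, scores)
        per_fold.append(m)
    return MetricReport(per_fold, plan.mode)


def write_report(report: MetricReport, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("metric\tmean\trsd_pct\tn_undefined\n")
        for m in METRIC_NAMES:
            fh.write(f"{m}\t{report.mean[m]:.6g}\t{report.rsd[m]:.6g}\t{report.n_undefined[m]}\n")
        fh.write(f"# mode: {report.mode}\n")
        for i, f in enumerate(report.per_fold):
            vals = "\t".join(f"{f[m]:.6g}" for m in METRIC_NAMES)
            fh.write(f"# fold\t{i}\t{vals}\n")
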