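"""Deduplicated stratified cross-validation and the evaluation metric suite.

Model stability is assessed by stratified k-fold cross-validation (k=3 in
the study setting) on a deduplicated dataset: identical sentences are
removed before the partition so no normalized text appears in two folds.
Metrics are one-vs-rest per status — precision, recall, specificity and
F-score — plus two aggregates over the evaluated statuses only:

    balanced accuracy = (1/C) sum_c [ (TP_c/(TP_c+FN_c) + TN_c/(TN_c+FP_c)) / 2 ]
    macro F           = (1/C) sum_c F1(c)

Undefined ratios (0/0) are reported as NaN (not applicable) and excluded
from the aggregates with a flag, never coerced to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import Sentence, normalized_key
from .model import Extractor, LabeledDataset

__all__ = [
    "FoldPlan",
    "MetricsReport",
    "CrossValidationResult",
    "ComparisonReport",
    "EvaluationError",
    "make_folds",
    "compute_metrics",
    "cross_validate",
    "compare_extractors",
    "paired_fold_test",
    "breakdown_by_doctype",
    "audit_patient_overlap",
]


class EvaluationError(ValueError):
    """Raised for invalid evaluation inputs."""


@dataclass
class FoldPlan:
    k: int
    assignment: dict[str, int]  # sent_id -> fold index
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [sid for sid, f in self.assignment.items() if f == fold]


def make_folds(dataset: LabeledDataset, k: int = 3, seed: int = 0) -> FoldPlan:
    """Stratified fold assignment over the dataset's included items.

    Preconditions: the dataset carries no duplicate normalized texts and
    every included class has at least k samples.  Items are shuffled within
    class by the seed and dealt round-robin; the starting fold rotates
    across classes so fold sizes differ by at most one both per class and
    overall.
    """
    items = dataset.included
    keys = [normalized_key(s.text) for s, _ in items]
    if len(set(keys)) != len(keys):
        raise EvaluationError(
            "dataset contains duplicate sentences; deduplicate before folding"
        )
    by_class: dict[str, list[str]] = {}
    for s, lab in items:
        by_class.setdefault(lab, []).append(s.sent_id)
    if k != len(items):  # k == n is leave-one-out: singleton folds are valid
        for lab, ids in by_class.items():
            if len(ids) < k:
                raise EvaluationError(
                    f"class {lab!r} has {len(ids)} samples, fewer than k={k}; "
                    "drop it per min_per_class before folding"
                )
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    offset = 0
    for lab in sorted(by_class):
        ids = list(by_class[lab])
        rng.shuffle(ids)
        for j, sid in enumerate(ids):
            assignment[sid] = (offset + j) % k
        offset = (offset + len(ids)) % k
    return FoldPlan(k=k, assignment=assignment, seed=seed)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Per-status one-vs-rest metrics plus aggregates over evaluated statuses.

    ``per_status`` is a DataFrame indexed by status with columns precision,
    recall, specificity, f_score, support; NaN marks not-applicable cells.
    ``undefined`` lists (status, metric) pairs excluded from aggregates.
    """

    per_status: pd.DataFrame
    balanced_accuracy: float
    macro_f: float
    evaluated_statuses: tuple[str, ...]
    n_items: int
    undefined: list[tuple[str, str]] = field(default_factory=list)


def _ratio(num: int, den: int) -> float:
    return num / den if den else float("nan")


def compute_metrics(
    gold: Mapping[str, str],
    predicted: Mapping[str, str],
    evaluated_statuses: Sequence[str] | None = None,
) -> MetricsReport:
    """One-vs-rest confusion metrics over sentences present in both mappings.

    ``evaluated_statuses`` defaults to the statuses with at least one gold
    sample; aggregates average over these only.
    """
    if set(gold) != set(predicted):
        missing = sorted(set(gold) ^ set(predicted))
        raise EvaluationError(f"gold and predictions cover different sentences: {missing[:5]}")
    if not gold:
        raise EvaluationError("empty evaluation set")
    ids = list(gold)
    g = [gold[i] for i in ids]
    p = [predicted[i] for i in ids]
    n = len(ids)
    if evaluated_statuses is None:
        evaluated = tuple(sorted(set(g)))
    else:
        evaluated = tuple(evaluated_statuses)
    classes = sorted(set(g) | set(p) | set(evaluated))

    rows = {}
    undefined: list[tuple[str, str]] = []
    ba_terms: list[float] = []
    f_terms: list[float] = []
    for c in classes:
        tp = sum(1 for x, y in zip(g, p) if x == c and y == c)
        fp = sum(1 for x, y in zip(g, p) if x != c and y == c)
        fn = sum(1 for x, y in zip(g, p) if x == c and y != c)
        tn = n - tp - fp - fn
        prec = _ratio(tp, tp + fp)
        rec = _ratio(tp, tp + fn)
        spec = _ratio(tn, tn + fp)
        if np.isnan(prec) or np.isnan(rec) or (prec + rec) == 0:
            f = float("nan") if (np.isnan(prec) or np.isnan(rec)) else 0.0
        else:
            f = 2 * prec * rec / (prec + rec)
        rows[c] = {
            "precision": prec,
            "recall": rec,
            "specificity": spec,
            "f_score": f,
            "support": tp + fn,
        }
        if c in evaluated:
            for mname, val in (("precision", prec), ("recall", rec),
                               ("specificity", spec), ("f_score", f)):
                if np.isnan(val):
                    undefined.append((c, mname))
            if not (np.isnan(rec) or np.isnan(spec)):
                ba_terms.append((rec + spec) / 2.0)
            if not np.isnan(f):
                f_terms.append(f)
    per_status = pd.DataFrame.from_dict(rows, orient="index")
    per_status.index.name = "status"
    return MetricsReport(
        per_status=per_status,
        balanced_accuracy=float(np.mean(ba_terms)) if ba_terms else float("nan"),
        macro_f=float(np.mean(f_terms)) if f_terms else float("nan"),
        evaluated_statuses=evaluated,
        n_items=n,
        undefined=undefined,
    )


# ---------------------------------------------------------------------------
# Cross-validation and comparison
# ---------------------------------------------------------------------------


@dataclass
class CrossValidationResult:
    reports: list[MetricsReport]
    macro_f_mean: float
    macro_f_sd: float
    plan: FoldPlan
    #: per fold: (gold, predicted) sentence->label mappings of the validation set
    fold_predictions: list[tuple[dict[str, str], dict[str, str]]] = field(default_factory=list)

    @property
    def fold_macro_f(self) -> list[float]:
        return [r.macro_f for r in self.reports]


BackendFactory = Callable[[list[tuple[Sentence, str]]], Extractor]


def cross_validate(
    dataset: LabeledDataset,
    backend_factory: BackendFactory,
    k: int = 3,
    seed: int = 0,
    plan: FoldPlan | None = None,
) -> CrossValidationResult:
    """k train/validate rounds; mean and sample SD of macro F across folds.

    ``backend_factory`` receives the training items of a round and returns
    a fitted extractor.  The evaluated statuses of each round are the
    classes with gold support in its validation fold.
    """
    if plan is None:
        plan = make_folds(dataset, k=k, seed=seed)
    items = {s.sent_id: (s, lab) for s, lab in dataset.included}
    reports: list[MetricsReport] = []
    fold_predictions: list[tuple[dict[str, str], dict[str, str]]] = []
    for fold in range(plan.k):
        val_ids = [sid for sid in items if plan.assignment[sid] == fold]
        train_items = [items[sid] for sid in items if plan.assignment[sid] != fold]
        try:
            extractor = backend_factory(train_items)
        except Exception as exc:
            raise EvaluationError(f"training failed on fold {fold}: {exc}") from exc
        val_sents = [items[sid][0] for sid in val_ids]
        gold = {sid: items[sid][1] for sid in val_ids}
        pred = extractor.predict(val_sents)
        reports.append(compute_metrics(gold, pred))
        fold_predictions.append((gold, pred))
    fold_f = [r.macro_f for r in reports]
    sd = float(np.std(fold_f, ddof=1)) if len(fold_f) > 1 else float("nan")
    return CrossValidationResult(
        reports=reports,
        macro_f_mean=float(np.mean(fold_f)),
        macro_f_sd=sd,
        plan=plan,
        fold_predictions=fold_predictions,
    )


@dataclass
class ComparisonReport:
    """Mean/SD macro F per extractor on identical folds (one table row each)."""

    table: pd.DataFrame  # index extractor name; columns macro_f_mean, macro_f_sd
    fold_scores: dict[str, list[float]]


def compare_extractors(
    dataset: LabeledDataset,
    factories: Mapping[str, BackendFactory],
    k: int = 3,
    seed: int = 0,
) -> ComparisonReport:
    """Evaluate several backends on the same fold plan."""
    plan = make_folds(dataset, k=k, seed=seed)
    rows = {}
    fold_scores: dict[str, list[float]] = {}
    for name, factory in factories.items():
        cv = cross_validate(dataset, factory, k=k, seed=seed, plan=plan)
        rows[name] = {"macro_f_mean": cv.macro_f_mean, "macro_f_sd": cv.macro_f_sd}
        fold_scores[name] = cv.fold_macro_f
    return ComparisonReport(
        table=pd.DataFrame.from_dict(rows, orient="index"), fold_scores=fold_scores
    )


def paired_fold_test(scores_a: Sequence[float], scores_b: Sequence[float]):
    """Two-sided paired t test on per-fold macro F (k-1 degrees of freedom)."""
    if len(scores_a) != len(scores_b) or len(scores_a) < 2:
        raise EvaluationError("paired test needs two equal-length fold score lists (k >= 2)")
    return stats.ttest_rel(scores_a, scores_b)


# ---------------------------------------------------------------------------
# Breakdowns and audits
# ---------------------------------------------------------------------------


def breakdown_by_doctype(
    gold: Mapping[str, str],
    predicted: Mapping[str, str],
    sentences: Sequence[Sentence],
) -> pd.DataFrame:
    """Per (doc_type, status) F-score table.

    Cells with neither gold nor predicted support in that document-type
    slice are NaN (not available), never 0.
    """
    by_id = {s.sent_id: s for s in sentences}
    doctypes = sorted({by_id[i].doc_type for i in gold if i in by_id})
    statuses = sorted(set(gold.values()) | set(predicted.values()))
    out = pd.DataFrame(index=statuses, columns=doctypes, dtype=float)
    for dt in doctypes:
        ids = [i for i in gold if i in by_id and by_id[i].doc_type == dt]
        g = {i: gold[i] for i in ids}
        p = {i: predicted[i] for i in ids}
        if not ids:
            continue
        rep = compute_metrics(g, p, evaluated_statuses=statuses)
        for st in statuses:
            support = sum(1 for i in ids if g[i] == st or p[i] == st)
            if support == 0:
                continue
            if st in rep.per_status.index:
                out.loc[st, dt] = rep.per_status.loc[st, "f_score"]
    return out


def audit_patient_overlap(
    plan: FoldPlan, sentences: Sequence[Sentence]
) -> dict[int, float]:
    """Fraction of each validation fold's sentences whose patient also
    appears in the corresponding training folds (a leakage diagnostic —
    folds are sentence-stratified, not patient-partitioned)."""
    by_id = {s.sent_id: s for s in sentences}
    patients_by_fold: dict[int, set[str]] = {f: set() for f in range(plan.k)}
    for sid, f in plan.assignment.items():
        if sid in by_id:
            patients_by_fold[f].add(by_id[sid].patient_id)
    out: dict[int, float] = {}
    for fold in range(plan.k):
        val = [sid for sid, f in plan.assignment.items() if f == fold and sid in by_id]
        train_patients = set().union(
            *(patients_by_fold[f] for f in range(plan.k) if f != fold)
        ) if plan.k > 1 else set()
        if not val:
            out[fold] = float("nan")
            continue
        hits = sum(1 for sid in val if by_id[sid].patient_id in train_patients)
        out[fold] = hits / len(val)
    return out
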