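"""Stratified folds, metric suite, cross-validation, breakdowns, audits."""

import math

import numpy as np
import pytest

from msep.evaluate import (
    EvaluationError,
    audit_patient_overlap,
    breakdown_by_doctype,
    compute_metrics,
    cross_validate,
    make_folds,
    paired_fold_test,
)
from msep.model import LabeledDataset, LossSpec, RulesExtractor, train_linear
from msep.rules import builtin_ruleset
from msep.synth import SynthConfig, generate, labeled_dataset
from tests.conftest import make_sentence


def dataset_from_labels(labels, condition="diabetes", min_per_class=1, **sent_kw):
    items = [
        (make_sentence(f"texte numéro {i}.", sent_id=f"s{i}", **sent_kw), lab)
        for i, lab in enumerate(labels)
    ]
    return LabeledDataset(items, condition, min_per_class=min_per_class)


# ---------------------------------------------------------------------------
# Independent brute-force metric oracle
# ---------------------------------------------------------------------------


def naive_metrics(gold: dict, pred: dict):
    """Per-class one-vs-rest counting by explicit loops (test oracle)."""
    ids = list(gold)
    classes = sorted(set(gold.values()) | set(pred.values()))
    out = {}
    for c in classes:
        tp = fp = fn = tn = 0
        for i in ids:
            g_is, p_is = gold[i] == c, pred[i] == c
            if g_is and p_is:
                tp += 1
            elif not g_is and p_is:
                fp += 1
            elif g_is and not p_is:
                fn += 1
            else:
                tn += 1
        prec = tp / (tp + fp) if tp + fp else float("nan")
        rec = tp / (tp + fn) if tp + fn else float("nan")
        spec = tn / (tn + fp) if tn + fp else float("nan")
        if math.isnan(prec) or math.isnan(rec):
            f = float("nan")
        elif prec + rec == 0:
            f = 0.0
        else:
            f = 2 * prec * rec / (prec + rec)
        out[c] = dict(precision=prec, recall=rec, specificity=spec, f_score=f)
    return out


def random_fixture(rng, n_max=40):
    n = int(rng.integers(4, n_max))
    classes = ["present", "absent", "former", "unknown"][: int(rng.integers(2, 5))]
    gold = {f"s{i}": str(rng.choice(classes)) for i in range(n)}
    pred = {f"s{i}": str(rng.choice(classes)) for i in range(n)}
    return gold, pred


class TestComputeMetrics:
    def test_perfect_predictions(self):
        gold = {"a": "present", "b": "absent", "c": "unknown"}
        rep = compute_metrics(gold, dict(gold))
        assert rep.macro_f == 1.0 and rep.balanced_accuracy == 1.0
        assert (rep.per_status[["precision", "recall", "f_score"]] == 1.0).all().all()

    def test_hand_built_confusion_tables(self):
        gold = {"1": "P", "2": "P", "3": "A", "4": "U"}
        pred = {"1": "P", "2": "A", "3": "A", "4": "U"}
        rep = compute_metrics(gold, pred)
        assert rep.per_status.loc["P", "f_score"] == pytest.approx(2 / 3)
        assert rep.per_status.loc["A", "f_score"] == pytest.approx(2 / 3)
        assert rep.per_status.loc["U", "f_score"] == 1.0
        assert rep.macro_f == pytest.approx(0.7778, abs=1e-4)
        assert rep.balanced_accuracy == pytest.approx(0.8611, abs=1e-4)

    def test_agrees_with_naive_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            gold, pred = random_fixture(rng)
            rep = compute_metrics(gold, pred, evaluated_statuses=sorted(set(gold.values())))
            oracle = naive_metrics(gold, pred)
            for c, m in oracle.items():
                for name, val in m.items():
                    got = rep.per_status.loc[c, name]
                    if math.isnan(val):
                        assert math.isnan(got)
                    else:
                        assert got == pytest.approx(val, abs=1e-12)

    def test_single_class_reduction(self):
        """With one evaluated class, balanced accuracy reduces to
        (sensitivity+specificity)/2 and macro F to that class's F."""
        gold = {"1": "P", "2": "P", "3": "U", "4": "U", "5": "P"}
        pred = {"1": "P", "2": "U", "3": "U", "4": "P", "5": "P"}
        rep = compute_metrics(gold, pred, evaluated_statuses=["P"])
        row = rep.per_status.loc["P"]
        assert rep.balanced_accuracy == pytest.approx((row.recall + row.specificity) / 2)
        assert rep.macro_f == pytest.approx(row.f_score)

    def test_undefined_ratios_excluded_not_zeroed(self):
        gold = {"1": "P", "2": "P"}
        pred = {"1": "P", "2": "P"}
        rep = compute_metrics(gold, pred, evaluated_statuses=["P", "A"])
        assert math.isnan(rep.per_status.loc["A", "recall"])
        assert ("A", "recall") in rep.undefined
        assert rep.macro_f == 1.0  # A's NaN F excluded, not counted as 0

    def test_excluding_unsupported_statuses_preserves_others(self):
        rng = np.random.default_rng(3)
        gold, pred = random_fixture(rng)
        present = sorted(set(gold.values()))
        rep_all = compute_metrics(gold, pred, evaluated_statuses=present + ["ghost"])
        rep_sub = compute_metrics(gold, pred, evaluated_statuses=present)
        for c in present:
            for m in ("precision", "recall", "f_score"):
                a, b = rep_all.per_status.loc[c, m], rep_sub.per_status.loc[c, m]
                assert (math.isnan(a) and math.isnan(b)) or a == b

    def test_mismatched_sets_rejected(self):
        with pytest.raises(EvaluationError):
            compute_metrics({"a": "P"}, {"b": "P"})


class TestMakeFolds:
    def test_three_by_three_perfect_stratification(self):
        ds = dataset_from_labels(["a", "a", "a", "b", "b", "b", "c", "c", "c"])
        plan = make_folds(ds, k=3, seed=0)
        for fold in range(3):
            ids = plan.fold_ids(fold)
            labs = sorted(dict(
                (s.sent_id, lab) for s, lab in ds.items
            )[i] for i in ids)
            assert labs == ["a", "b", "c"]

    def test_duplicates_rejected(self):
        items = [(make_sentence("même texte.", sent_id=f"s{i}"), "a") for i in range(6)]
        items += [(make_sentence(f"autre {i}.", sent_id=f"t{i}"), "b") for i in range(6)]
        ds = LabeledDataset(items, "x", min_per_class=1)
        with pytest.raises(EvaluationError, match="duplicate"):
            make_folds(ds, k=3, seed=0)

    def test_small_class_error_names_it(self):
        ds = dataset_from_labels(["a"] * 6 + ["rare"] * 2)
        with pytest.raises(EvaluationError, match="rare"):
            make_folds(ds, k=3, seed=0)

    def test_proportions_within_one_sample(self):
        rng = np.random.default_rng(1)
        labels = ["a"] * 70 + ["b"] * 20 + ["c"] * 10
        rng.shuffle(labels)
        ds = dataset_from_labels(labels)
        plan = make_folds(ds, k=3, seed=4)
        by_id = {s.sent_id: lab for s, lab in ds.items}
        sizes = []
        for fold in range(3):
            ids = plan.fold_ids(fold)
            sizes.append(len(ids))
            for lab, total in (("a", 70), ("b", 20), ("c", 10)):
                got = sum(1 for i in ids if by_id[i] == lab)
                assert abs(got - total / 3) <= 1
        assert max(sizes) - min(sizes) <= 1

    def test_overall_balance_with_aligned_remainders(self):
        # two classes of 4 at k=3: naive per-class dealing gives fold sizes
        # (4,2,2); the rotating offset must keep the overall spread <= 1
        ds = dataset_from_labels(["a"] * 4 + ["b"] * 4)
        plan = make_folds(ds, k=3, seed=0)
        sizes = [len(plan.fold_ids(f)) for f in range(3)]
        assert max(sizes) - min(sizes) <= 1

    def test_deterministic_under_seed(self):
        ds = dataset_from_labels(["a"] * 9 + ["b"] * 9)
        assert make_folds(ds, 3, 7).assignment == make_folds(ds, 3, 7).assignment
        assert make_folds(ds, 3, 7).assignment != make_folds(ds, 3, 8).assignment

    def test_no_normalized_key_leakage_after_dedup(self):
        corpus = generate(SynthConfig(
            n_documents=60, duplicate_rate=0.2, seed=2,
            conditions={"smoking": {"present": 0.2, "absent": 0.2, "former": 0.1}},
        ))
        ds = labeled_dataset(corpus, "smoking").deduplicated()
        plan = make_folds(ds, k=3, seed=0)
        from msep.corpus import normalized_key

        key_fold = {}
        by_id = {s.sent_id: s for s, _ in ds.included}
        for sid, fold in plan.assignment.items():
            key = normalized_key(by_id[sid].text)
            assert key_fold.setdefault(key, fold) == fold


class TestCrossValidate:
    def test_rules_backend_on_clean_corpus_is_perfect(self):
        corpus = generate(SynthConfig(
            n_documents=80, seed=4,
            conditions={"smoking": {"present": 0.15, "absent": 0.1, "former": 0.1}},
        ))
        ds = labeled_dataset(corpus, "smoking").deduplicated()
        cv = cross_validate(ds, lambda items: RulesExtractor(builtin_ruleset("smoking")),
                            k=3, seed=0)
        assert cv.macro_f_mean == 1.0 and cv.macro_f_sd == 0.0

    def test_leave_one_out_boundary(self):
        ds = dataset_from_labels(["a", "b"] * 3)
        cv = cross_validate(ds, lambda items: RulesExtractor(builtin_ruleset("smoking")),
                            k=6, seed=0)
        assert len(cv.reports) == 6

    def test_paired_fold_test_runs(self):
        res = paired_fold_test([0.9, 0.92, 0.91], [0.85, 0.86, 0.88])
        assert res.pvalue < 0.1

    def test_paired_test_input_validation(self):
        with pytest.raises(EvaluationError):
            paired_fold_test([0.9], [0.8])


class TestBreakdownAndAudit:
    def test_single_doctype_single_column(self):
        ds = dataset_from_labels(["P", "P", "U"], doc_type="medical_reports")
        gold = {s.sent_id: lab for s, lab in ds.items}
        table = breakdown_by_doctype(gold, dict(gold), [s for s, _ in ds.items])
        assert list(table.columns) == ["medical_reports"]
        assert table.loc["P", "medical_reports"] == 1.0

    def test_unsupported_cells_are_na_never_zero(self):
        sents = [make_sentence("a.", sent_id="s1", doc_type="imaging_reports"),
                 make_sentence("b.", sent_id="s2", doc_type="medical_reports")]
        gold = {"s1": "P", "s2": "U"}
        table = breakdown_by_doctype(gold, dict(gold), sents)
        assert math.isnan(table.loc["P", "medical_reports"])
        assert math.isnan(table.loc["U", "imaging_reports"])

    def test_matches_filtered_recomputation(self):
        rng = np.random.default_rng(9)
        sents, gold, pred = [], {}, {}
        for i in range(60):
            dt = "medical_reports" if i % 2 else "daily_notes"
            s = make_sentence(f"texte {i}.", sent_id=f"s{i}", doc_type=dt)
            sents.append(s)
            gold[s.sent_id] = str(rng.choice(["P", "A", "U"]))
            pred[s.sent_id] = str(rng.choice(["P", "A", "U"]))
        table = breakdown_by_doctype(gold, pred, sents)
        for dt in ("medical_reports", "daily_notes"):
            ids = [s.sent_id for s in sents if s.doc_type == dt]
            sliced = compute_metrics({i: gold[i] for i in ids}, {i: pred[i] for i in ids},
                                     evaluated_statuses=["P", "A", "U"])
            for st in ("P", "A", "U"):
                val = table.loc[st, dt]
                if not math.isnan(val):
                    assert val == pytest.approx(sliced.per_status.loc[st, "f_score"])

    def test_patient_overlap_extremes(self):
        one = dataset_from_labels(["a"] * 6 + ["b"] * 6, patient_id="p0")
        plan = make_folds(one, k=3, seed=0)
        overlap = audit_patient_overlap(plan, [s for s, _ in one.items])
        assert all(v == 1.0 for v in overlap.values())

        # patients partitioned exactly by fold -> overlap 0
        items = []
        for fold in range(3):
            for j in range(4):
                items.append((make_sentence(f"t {fold} {j}.", sent_id=f"f{fold}j{j}",
                                            patient_id=f"p{fold}"), "a"))
        plan0 = make_folds(LabeledDataset(items, "x", min_per_class=1), k=3, seed=0)
        # force the exact patient partition
        plan0.assignment = {f"f{f}j{j}": f for f in range(3) for j in range(4)}
        overlap0 = audit_patient_overlap(plan0, [s for s, _ in items])
        assert all(v == 0.0 for v in overlap0.values())

    def test_patient_overlap_hand_counted(self):
        items = [
            (make_sentence("a.", sent_id="s0", patient_id="pA"), "x"),
            (make_sentence("b.", sent_id="s1", patient_id="pA"), "x"),
            (make_sentence("c.", sent_id="s2", patient_id="pB"), "x"),
            (make_sentence("d.", sent_id="s3", patient_id="pC"), "x"),
        ]
        from msep.evaluate import FoldPlan

        plan = FoldPlan(k=2, assignment={"s0": 0, "s1": 1, "s2": 0, "s3": 1}, seed=0)
        overlap = audit_patient_overlap(plan, [s for s, _ in items])
        # fold0 validation {s0 (pA), s2 (pB)}; training patients {pA, pC} -> 1/2
        # fold1 validation {s1 (pA), s3 (pC)}; training patients {pA, pB} -> 1/2
        assert overlap == {0: 0.5, 1: 0.5}


class TestLinearOnSynthetic:
    def test_noisy_corpus_heldout_macro_f(self):
        """Linear backend beats 0.90 macro F at 10% cue noise, k=3."""
        corpus = generate(SynthConfig(
            n_documents=160, sentences_per_document=8, cue_noise=0.10, seed=11,
            conditions={"diabetes": {"present": 0.18, "absent": 0.12}},
        ))
        ds = labeled_dataset(corpus, "diabetes").deduplicated()
        cv = cross_validate(
            ds,
            lambda items: train_linear(
                LabeledDataset(list(items), "diabetes"), LossSpec(hash_dim=2**15)
            ),
            k=3, seed=1,
        )
        assert cv.macro_f_mean >= 0.90
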