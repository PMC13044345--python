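"""Cohen's kappa, agreement gating, disagreements, correction, timing."""

import math

import numpy as np
import pytest

from msep.annotate import (
    AgreementResult,
    AnnotationError,
    AnnotationRecord,
    CorrectionPlan,
    agreement_gate,
    annotation_time_summary,
    apply_corrections,
    cohen_kappa,
    find_disagreements,
    select_for_revision,
)


def records(labels, annotator, condition="smoking", durations=None):
    durations = durations or [1.0] * len(labels)
    return [
        AnnotationRecord(f"s{i}", annotator, condition, lab, dur)
        for i, (lab, dur) in enumerate(zip(labels, durations))
    ]


# 10 items: 4 agree-present, 4 agree-unknown, 2 crossed.
# Hand contingency: [[4,1],[1,4]] -> Po=0.8, marginals (0.5,0.5) both
# -> Pe=0.5 -> kappa=(0.8-0.5)/0.5=0.6.
KAPPA_A = ["present"] * 4 + ["unknown"] * 4 + ["present", "unknown"]
KAPPA_B = ["present"] * 4 + ["unknown"] * 4 + ["unknown", "present"]


class TestCohenKappa:
    def test_identical_vectors(self):
        res = cohen_kappa(records(KAPPA_A, "a"), records(KAPPA_A, "b"), "smoking")
        assert res.kappa == 1.0 and res.po == 1.0

    def test_hand_enumerated_contingency(self):
        res = cohen_kappa(records(KAPPA_A, "a"), records(KAPPA_B, "b"), "smoking")
        assert res.po == pytest.approx(0.8)
        assert res.pe == pytest.approx(0.5)
        assert res.kappa == pytest.approx(0.6)
        assert res.contingency.loc["present", "present"] == 4
        assert res.contingency.loc["unknown", "present"] == 1

    def test_independent_uniform_labels_give_kappa_near_zero(self):
        rng = np.random.default_rng(0)
        n = 20000
        la = rng.choice(["present", "absent"], size=n).tolist()
        lb = rng.choice(["present", "absent"], size=n).tolist()
        res = cohen_kappa(records(la, "a"), records(lb, "b"), "smoking")
        assert abs(res.kappa) < 0.03  # ~3 SD at this n

    def test_matches_sklearn_on_random_fixtures(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            la = rng.choice(["present", "absent", "unknown"], size=n).tolist()
            lb = rng.choice(["present", "absent", "unknown"], size=n).tolist()
            if len(set(la)) == 1 and la == lb:
                continue  # Pe=1 convention differs by design
            res = cohen_kappa(records(la, "a"), records(lb, "b"), "smoking")
            assert res.kappa == pytest.approx(cohen_kappa_score(la, lb), abs=1e-12)

    def test_relabeling_invariance(self):
        mapping = {"present": "X", "unknown": "Y"}
        res1 = cohen_kappa(records(KAPPA_A, "a"), records(KAPPA_B, "b"), "smoking")
        res2 = cohen_kappa(
            records([mapping[l] for l in KAPPA_A], "a"),
            records([mapping[l] for l in KAPPA_B], "b"),
            "smoking",
        )
        assert res1.kappa == pytest.approx(res2.kappa)

    def test_pe_one_convention(self):
        res = cohen_kappa(records(["present"] * 5, "a"), records(["present"] * 5, "b"), "smoking")
        assert res.pe == 1.0 and res.kappa == 1.0

    def test_mismatched_sets_error_lists_difference(self):
        ra = records(["present"] * 3, "a")
        rb = records(["present"] * 2, "b")
        with pytest.raises(AnnotationError, match="s2"):
            cohen_kappa(ra, rb, "smoking")

    def test_empty_overlap_is_an_error(self):
        with pytest.raises(AnnotationError):
            cohen_kappa([], records(["present"], "b"), "smoking")


class TestAgreementGate:
    @pytest.mark.parametrize(
        "kappa,threshold,expected",
        [(0.57, 0.8, False), (0.8, 0.8, True), (1.0, 0.99, True), (0.79999, 0.8, False)],
    )
    def test_gate(self, kappa, threshold, expected):
        res = AgreementResult(kappa=kappa, po=0, pe=0, n_items=1, contingency=None)
        assert agreement_gate(res, threshold) is expected

    def test_invalid_threshold(self):
        res = AgreementResult(kappa=1.0, po=1, pe=0, n_items=1, contingency=None)
        with pytest.raises(ValueError):
            agreement_gate(res, 0.0)


class TestDisagreements:
    def test_crossed_items_of_kappa_fixture(self):
        out = find_disagreements(records(KAPPA_A, "a"), records(KAPPA_B, "b"), "smoking")
        assert out == [("s8", "present", "unknown"), ("s9", "unknown", "present")]

    def test_count_equals_n_times_one_minus_po(self):
        ra, rb = records(KAPPA_A, "a"), records(KAPPA_B, "b")
        res = cohen_kappa(ra, rb, "smoking")
        assert len(find_disagreements(ra, rb, "smoking")) == round(
            res.n_items * (1 - res.po)
        )

    def test_identical_and_all_different(self):
        ra = records(["present", "absent"], "a")
        assert find_disagreements(ra, records(["present", "absent"], "b"), "smoking") == []
        assert len(find_disagreements(ra, records(["absent", "present"], "b"), "smoking")) == 2


class TestRevision:
    def test_term_containment_selection(self, sent_factory):
        sents = [
            sent_factory("Dyspnée au moindre effort."),
            sent_factory("Echographie avec une fraction d'éjection ventriculaire conservée."),
            sent_factory("Constantes stables."),
            sent_factory("Traitement poursuivi."),
            sent_factory("Pas de douleur."),
        ]
        plan = CorrectionPlan(ambiguous_terms=["fraction d'éjection"])
        assert select_for_revision(sents, plan) == [sents[1].sent_id]

    def test_absent_term_and_set_semantics(self, sent_factory):
        sents = [sent_factory("Un texte."), sent_factory("Douleur thoracique et dyspnée.")]
        assert select_for_revision(sents, CorrectionPlan(["absent partout"])) == []
        both = select_for_revision(sents, CorrectionPlan(["douleur", "dyspnée"]))
        assert both == [sents[1].sent_id]  # one sentence, listed once

    def test_empty_terms_error(self, sent_factory):
        with pytest.raises(AnnotationError):
            select_for_revision([sent_factory("x")], CorrectionPlan([]))

    def test_apply_corrections_archives_originals(self):
        ra = records(["present", "absent", "unknown"], "b")
        updated, archived = apply_corrections(ra, {"s1": "present"}, "v2")
        assert [r.label for r in updated] == ["present", "present", "unknown"]
        assert len(archived) == 1 and archived[0].label == "absent"
        assert updated[1].annotator_id.endswith("+v2")


class TestTimeSummary:
    def test_arithmetic(self):
        recs = records(["unknown", "unknown", "present"], "a", durations=[1, 1, 4])
        mean_all, mean_info = annotation_time_summary(recs)
        assert mean_all == 2.0 and mean_info == 4.0

    def test_all_unknown_informative_na(self):
        recs = records(["unknown"] * 3, "a", durations=[1, 2, 3])
        _, mean_info = annotation_time_summary(recs)
        assert math.isnan(mean_info)

    def test_lognormal_fixture_recovers_generator_means(self):
        # mean of lognormal(mu, sigma) with mu = ln(m) - sigma^2/2 is m
        rng = np.random.default_rng(3)
        sigma, m_unk, m_inf = 0.4, 1.5, 3.0
        n = 1000
        labels = ["unknown"] * n + ["present"] * n
        durs = np.concatenate([
            rng.lognormal(math.log(m_unk) - sigma**2 / 2, sigma, n),
            rng.lognormal(math.log(m_inf) - sigma**2 / 2, sigma, n),
        ])
        recs = records(labels, "a", durations=durs.tolist())
        mean_all, mean_info = annotation_time_summary(recs)
        assert mean_info == pytest.approx(m_inf, rel=0.05)
        assert mean_all == pytest.approx((m_unk + m_inf) / 2, rel=0.05)

    def test_gold_labels_override_record_labels(self):
        recs = records(["unknown", "unknown"], "a", durations=[1, 5])
        _, mean_info = annotation_time_summary(recs, gold_labels={"s1": "present"})
        assert mean_info == 5.0
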