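"""Synthetic clinical-corpus generator with exported gold labels.

Real clinical corpora for this task live in hospital data warehouses and
cannot be shipped.  This generator emulates the statistical structure the
pipeline assumes, with exact gold labels recorded at planting time:

* very sparse informative sentences (default per-condition prevalences in
  the sub-percent range of an unfiltered clinical corpus);
* strong class imbalance (absent much rarer than present for most
  conditions; ``former`` only for smoking);
* a skewed document-type mix (nursing procedures ~41%, medical reports
  ~23%, ...);
* duplicated sentences (re-emitted text under fresh ids, possibly other
  patients) and patient-level grouping of documents.

Sentences come from status-specific French templates whose keywords and
cues align with the shipped rule lexica, so at cue-noise 0 the rule
classifier recovers every planted label.  With probability ``cue_noise`` an
informative sentence instead uses a paraphrase template whose cue (or
keyword) lies outside the rule lexica — rules then err while a trained
classifier can still learn the paraphrase.  Clinical realism beyond cue
structure and sparsity is a non-goal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotate import AnnotationRecord
from .corpus import Document, Sentence
from .model import LabeledDataset

__all__ = [
    "SynthConfig",
    "GoldCorpus",
    "DurationModel",
    "generate",
    "simulate_annotators",
    "labeled_dataset",
    "default_doc_type_mix",
    "study_conditions",
]


def default_doc_type_mix() -> dict[str, float]:
    """Document-type mix of a typical hospital corpus (ratios of documents)."""
    return {
        "nursing_care_procedures": 0.41,
        "medical_reports": 0.23,
        "nursing_care_monitoring": 0.19,
        "daily_notes": 0.07,
        "imaging_reports": 0.04,
        "prescriptions": 0.02,
        "paramedical_care": 0.02,
        "administrative": 0.01,
        "pathology_reports": 0.01,
        "Other": 0.01,
    }


def study_conditions() -> dict[str, dict[str, float]]:
    """Default per-condition status prevalences (fractions of all sentences).

    Mirrors the unfiltered regime of the study corpus: informative
    prevalence 0.07%–0.75% per condition, absent rarer than present,
    ``former`` only for smoking, essentially no absent samples for COPD and
    family history of cancer.
    """
    return {
        "smoking": {"present": 0.0033, "absent": 0.0009, "former": 0.0033},
        "diabetes": {"present": 0.0022, "absent": 0.0003},
        "hypertension": {"present": 0.0070, "absent": 0.0005},
        "heart_failure": {"present": 0.0012, "absent": 0.0013},
        "copd": {"present": 0.0017},
        "family_cancer": {"present": 0.0007},
    }


@dataclass
class SynthConfig:
    """Generator parameters.  Per-condition prevalences must sum to <= 1;
    the remainder is filler (gold ``unknown`` for every condition)."""

    conditions: dict[str, dict[str, float]] = field(default_factory=study_conditions)
    cue_noise: float = 0.0
    doc_type_mix: dict[str, float] = field(default_factory=default_doc_type_mix)
    duplicate_rate: float = 0.0
    n_documents: int = 200
    sentences_per_document: float = 8.0
    n_patients: int = 40
    seed: int = 0
    language: str = "fr"

    def __post_init__(self) -> None:
        total = sum(p for cond in self.conditions.values() for p in cond.values())
        if total > 1.0:
            raise ValueError(f"condition prevalences sum to {total:.4f} > 1")
        for r, name in ((self.cue_noise, "cue_noise"), (self.duplicate_rate, "duplicate_rate")):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {r}")
        for cond, statuses in self.conditions.items():
            bank = _bank(self.language)
            if cond not in bank:
                raise ValueError(f"no template bank for condition {cond!r}")
            for st in statuses:
                if st not in bank[cond]["statuses"]:
                    raise ValueError(f"condition {cond!r} has no templates for status {st!r}")


@dataclass
class GoldCorpus:
    """Generated documents, sentences, gold labels and planted-count bookkeeping."""

    documents: list[Document]
    sentences: list[Sentence]
    labels: dict[str, dict[str, str]]  # condition -> sent_id -> status
    counts: dict[str, dict[str, int]]  # condition -> status -> planted count
    config: SynthConfig


# ---------------------------------------------------------------------------
# Template banks
# ---------------------------------------------------------------------------


def _de(kw: str) -> str:
    """French elision: 'de tabac' but 'd'hypertension'."""
    if not kw:
        return ""
    return ("d'" if kw[0].lower() in "aeiouyhé" else "de ") + kw


# Each condition entry: noun keywords usable in templates, per-status clean
# templates, and per-status noise (paraphrase) templates.  Clean templates
# are classified correctly by the shipped lexica; noise templates are not.
_FR_BANK: dict[str, dict] = {
    "smoking": {
        "keywords": ["tabac", "tabagisme"],
        "statuses": {
            "present": [
                "Tabagisme actif, environ {n} PA.",
                "Patient fumeur depuis {year}.",
                "Consommation de tabac estimée à {n} cigarettes par jour.",
                "Tabagisme pendant {n} ans, reprise récente malgré un sevrage en {year}.",
            ],
            "absent": [
                "Pas {dekw} retrouvé au bilan du {d}/{m}.",
                "Aucune consommation {dekw} signalée en {year}.",
                "Patient sans tabagisme connu ({year}).",
            ],
            "former": [
                "Sevrage du tabac en {year}.",
                "Tabagisme arrêté depuis {n} ans.",
                "Ancien fumeur, sevré en {year}.",
            ],
        },
        "noise": {
            "present": [
                "Consommation tabagique toujours d'actualité selon la famille de {n} cigarettes.",
            ],
            "absent": [
                "Le patient nie toute consommation {dekw} depuis {year}.",
                "Tabac : négatif au questionnaire du {d}/{m}.",
            ],
            "former": [
                "Fumait {n} cigarettes par jour autrefois, plus rien maintenant.",
            ],
        },
    },
    "diabetes": {
        "keywords": ["diabète", "diabète de type 2"],
        "statuses": {
            "present": [
                "Diabète connu depuis {year}, suivi régulier.",
                "Patient suivi pour diabète, HbA1c à {n} %.",
                "Diabète équilibré sous traitement depuis {year}.",
            ],
            "absent": [
                "Pas {dekw} connu ({year}).",
                "Absence {dekw} au bilan du {d}/{m}.",
                "Aucun diabète retrouvé en {year}.",
            ],
        },
        "noise": {
            "present": [
                "Glycémies élevées traitées depuis {year}, diabète probablement déséquilibré.",
            ],
            "absent": [
                "Le patient nie tout diabète au questionnaire du {d}/{m}.",
                "Diabète : négatif au dépistage de {year}.",
            ],
        },
    },
    "hypertension": {
        "keywords": ["HTA", "hypertension"],
        "statuses": {
            "present": [
                "HTA connue depuis {year}, traitée.",
                "Patient suivi pour hypertension depuis {year}.",
                "HTA équilibrée sous bithérapie depuis {year}.",
            ],
            "absent": [
                "Pas {dekw} connue ({year}).",
                "Absence {dekw} au bilan du {d}/{m}.",
                "Patient sans HTA documentée en {year}.",
            ],
        },
        "noise": {
            "present": [
                "Chiffres tensionnels élevés au contrôle du {d}/{m}, HTA vraisemblable.",
            ],
            "absent": [
                "Le patient nie toute HTA lors du contrôle du {d}/{m}.",
                "HTA : négatif au dépistage de {year}.",
            ],
        },
    },
    "heart_failure": {
        "keywords": ["insuffisance cardiaque"],
        "statuses": {
            "present": [
                "Insuffisance cardiaque connue depuis {year}.",
                "Patient suivi pour insuffisance cardiaque, FEVG {n} %.",
                "Décompensation cardiaque en {year}, traitement poursuivi.",
            ],
            "absent": [
                "Pas {dekw} retrouvée ({year}).",
                "Absence {dekw} au bilan du {d}/{m}.",
                "Aucune insuffisance cardiaque documentée en {year}.",
            ],
        },
        "noise": {
            "present": [
                "Tableau évocateur d'insuffisance cardiaque au vu de l'échographie du {d}/{m}.",
            ],
            "absent": [
                "Le patient nie toute insuffisance cardiaque au questionnaire du {d}/{m}.",
                "Insuffisance cardiaque : négatif à l'échographie de {year}.",
            ],
        },
    },
    "copd": {
        "keywords": ["BPCO"],
        "statuses": {
            "present": [
                "BPCO connue depuis {year}, stade {n}.",
                "Patient suivi pour BPCO depuis {year}.",
                "BPCO documentée aux EFR du {d}/{m}.",
            ],
            "absent": [
                "Pas {dekw} retrouvée ({year}).",
                "Absence {dekw} aux EFR du {d}/{m}.",
                "Aucune BPCO documentée en {year}.",
            ],
        },
        "noise": {
            "present": [
                "Trouble ventilatoire obstructif chronique aux EFR du {d}/{m}, BPCO retenue.",
            ],
            "absent": [
                "BPCO : négatif aux EFR du {d}/{m}.",
            ],
        },
    },
    "family_cancer": {
        "keywords": ["cancer"],
        "statuses": {
            "present": [
                "Antécédents familiaux de cancer chez le père ({year}).",
                "Cancer du côlon chez la mère en {year}.",
                "Antécédent familial de tumeur chez la soeur, diagnostiqué en {year}.",
            ],
        },
        "noise": {
            "present": [
                "Plusieurs cas de néo dans la famille depuis {year}.",
            ],
        },
    },
}

_FR_FILLERS = [
    "Constantes stables ce jour ({d}/{m}).",
    "Pansement refait à {h}h.",
    "Poursuite du traitement habituel depuis {year}.",
    "Bonne tolérance du traitement ce {d}/{m}.",
    "Patient calme cette nuit, relève de {h}h.",
    "Transmissions faites à l'équipe de {h}h.",
    "Kinésithérapie réalisée ce matin, séance de {n} minutes.",
    "Repas pris en totalité au déjeuner du {d}/{m}.",
    "Douleur évaluée à {n}/10 ce jour.",
    "Rendez-vous de contrôle prévu en {year}.",
    "Perfusion en cours, débit {n} mL/h.",
    "Surveillance biologique programmée le {d}/{m}.",
]

# Minimal English bank for portability demonstrations; the shipped rule
# lexica are French, so rule-recovery guarantees apply to the French bank.
_EN_BANK: dict[str, dict] = {
    "smoking": {
        "keywords": ["tobacco", "smoking"],
        "statuses": {
            "present": ["Active smoking, about {n} pack-years."],
            "absent": ["No tobacco use reported in {year}."],
            "former": ["Quit smoking in {year}."],
        },
        "noise": {"absent": ["Patient denies any tobacco use since {year}."]},
    },
}

_EN_FILLERS = [
    "Vital signs stable today ({d}/{m}).",
    "Dressing changed at {h}:00.",
    "Pain rated {n}/10 this morning.",
]


def _bank(language: str) -> dict[str, dict]:
    if language == "fr":
        return _FR_BANK
    if language == "en":
        return _EN_BANK
    raise ValueError(f"unknown template language {language!r}")


def _fillers(language: str) -> list[str]:
    return _FR_FILLERS if language == "fr" else _EN_FILLERS


def _fill(template: str, kw: str, rng: np.random.Generator) -> str:
    return template.format(
        kw=kw,
        dekw=_de(kw),
        n=int(rng.integers(1, 40)),
        year=int(rng.integers(1985, 2024)),
        d=int(rng.integers(1, 29)),
        m=int(rng.integers(1, 13)),
        h=int(rng.integers(6, 23)),
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate(config: SynthConfig) -> GoldCorpus:
    """Build a gold-labeled corpus; deterministic for a given config + seed."""
    rng = np.random.default_rng(config.seed)
    bank = _bank(config.language)
    fillers = _fillers(config.language)

    # planting distribution over (condition, status) events plus filler
    events: list[tuple[str, str]] = []
    probs: list[float] = []
    for cond, statuses in config.conditions.items():
        for st, p in statuses.items():
            events.append((cond, st))
            probs.append(p)
    p_filler = 1.0 - sum(probs)
    cum = np.cumsum(probs)

    dt_names = list(config.doc_type_mix)
    dt_probs = np.array([config.doc_type_mix[d] for d in dt_names], dtype=float)
    dt_probs = dt_probs / dt_probs.sum()

    conditions = list(config.conditions)
    counts: dict[str, dict[str, int]] = {
        c: {s: 0 for s in ("present", "absent", "former", "unknown")} for c in conditions
    }
    documents: list[Document] = []
    sentences: list[Sentence] = []
    labels: dict[str, dict[str, str]] = {c: {} for c in conditions}
    history: list[tuple[str, dict[str, str]]] = []  # (text, per-condition labels)

    for di in range(config.n_documents):
        doc_id = f"D{di:05d}"
        patient_id = f"P{int(rng.integers(0, config.n_patients)):04d}"
        doc_type = dt_names[int(rng.choice(len(dt_names), p=dt_probs))]
        n_sent = max(1, int(rng.poisson(config.sentences_per_document)))
        texts: list[str] = []
        sent_labels: list[dict[str, str]] = []
        for _ in range(n_sent):
            if history and rng.random() < config.duplicate_rate:
                text, lab = history[int(rng.integers(0, len(history)))]
            else:
                u = rng.random()
                j = int(np.searchsorted(cum, u, side="right"))
                if j < len(events):
                    cond, st = events[j]
                    entry = bank[cond]
                    noise_bank = entry.get("noise", {}).get(st, [])
                    use_noise = noise_bank and rng.random() < config.cue_noise
                    pool = noise_bank if use_noise else entry["statuses"][st]
                    template = pool[int(rng.integers(0, len(pool)))]
                    kw = entry["keywords"][int(rng.integers(0, len(entry["keywords"])))]
                    text = _fill(template, kw, rng)
                    lab = {cond: st}
                else:
                    template = fillers[int(rng.integers(0, len(fillers)))]
                    text = _fill(template, "", rng)
                    lab = {}
                history.append((text, lab))
            texts.append(text)
            sent_labels.append(lab)

        doc_text = " ".join(texts)
        documents.append(
            Document(doc_id=doc_id, patient_id=patient_id, doc_type=doc_type, text=doc_text)
        )
        pos = 0
        for text, lab in zip(texts, sent_labels):
            start = doc_text.index(text, pos)
            end = start + len(text)
            pos = end
            sent = Sentence(
                sent_id=f"{doc_id}:{start}",
                doc_id=doc_id,
                patient_id=patient_id,
                doc_type=doc_type,
                text=text,
                span=(start, end),
            )
            sentences.append(sent)
            for cond in conditions:
                st = lab.get(cond, "unknown")
                labels[cond][sent.sent_id] = st
                counts[cond][st] += 1

    return GoldCorpus(
        documents=documents,
        sentences=sentences,
        labels=labels,
        counts=counts,
        config=config,
    )


def labeled_dataset(
    corpus: GoldCorpus, condition: str, min_per_class: int = 3
) -> LabeledDataset:
    """Gold labels of one condition as a training/evaluation dataset."""
    gold = corpus.labels[condition]
    items = [(s, gold[s.sent_id]) for s in corpus.sentences]
    return LabeledDataset(items=items, condition=condition, min_per_class=min_per_class)


# ---------------------------------------------------------------------------
# Simulated annotators
# ---------------------------------------------------------------------------


@dataclass
class DurationModel:
    """Lognormal annotation times: ``unknown`` sentences are dismissed faster
    than informative ones (means in seconds per sentence)."""

    unknown_mean: float = 1.5
    informative_mean: float = 3.0
    sigma: float = 0.4

    def draw(self, informative: bool, rng: np.random.Generator) -> float:
        mean = self.informative_mean if informative else self.unknown_mean
        mu = math.log(mean) - 0.5 * self.sigma**2
        return float(rng.lognormal(mu, self.sigma))


def simulate_annotators(
    gold: GoldCorpus,
    condition: str,
    disagreement_rate: float = 0.0,
    duration_model: DurationModel | None = None,
    seed: int = 0,
    label_set: Sequence[str] | None = None,
    sentences: Sequence[Sentence] | None = None,
) -> tuple[list[AnnotationRecord], list[AnnotationRecord]]:
    """Two annotation streams: A reproduces gold; B flips each label to a
    uniformly random other label with probability ``disagreement_rate``."""
    if not 0.0 <= disagreement_rate < 1.0:
        raise ValueError(f"disagreement_rate must be in [0, 1), got {disagreement_rate}")
    dm = duration_model or DurationModel()
    rng = np.random.default_rng(seed)
    gold_labels = gold.labels[condition]
    if label_set is None:
        declared = set(gold.config.conditions.get(condition, ())) | {"unknown"}
        label_set = sorted(declared | set(gold_labels.values()))
    pool = sentences if sentences is not None else gold.sentences
    rec_a: list[AnnotationRecord] = []
    rec_b: list[AnnotationRecord] = []
    for s in pool:
        lab = gold_labels[s.sent_id]
        informative = lab != "unknown"
        rec_a.append(
            AnnotationRecord(s.sent_id, "annotator_a", condition, lab, dm.draw(informative, rng))
        )
        lab_b = lab
        if rng.random() < disagreement_rate:
            others = [l for l in label_set if l != lab]
            if others:
                lab_b = others[int(rng.integers(0, len(others)))]
        rec_b.append(
            AnnotationRecord(s.sent_id, "annotator_b", condition, lab_b, dm.draw(informative, rng))
        )
    return rec_a, rec_b
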