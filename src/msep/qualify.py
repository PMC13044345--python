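"""Data qualification: control reservation, preannotation filtering, bias stats.

Informative sentences (those carrying a present/absent/former status) are
extremely sparse in raw clinical corpora — well under 1% before filtering.
Qualification raises their density for annotation: a small control subset is
reserved uniformly at random *before* any preannotation-based decision (the
unfiltered subset, US, used to audit selection bias), then sentences
preannotated ``unknown`` are down-sampled from the remaining pool (the
preannotated-filtered set, PS).

Two statistics quantify the effect per condition:

* proportion(status) = c(status) / c(present, absent, former) — the share of
  a relevant status among relevant samples (``unknown`` excluded from both
  numerator and denominator);
* prevalence = c(present, absent, former) / c(all four statuses) — the
  density of relevant samples, ``unknown`` included in the denominator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import Sentence
from .rules import RuleDecision

__all__ = [
    "QualifyConfig",
    "DistributionReport",
    "split_control",
    "filter_by_preannotation",
    "status_proportions",
    "prevalence",
    "distribution_report",
]

RELEVANT_STATUSES = ("present", "absent", "former")


@dataclass
class QualifyConfig:
    """Parameters of the qualification step.

    ``unknown_keep_fraction`` defaults to 0.05 so that expected post-filter
    prevalence p/(p + 0.05(1-p)) lands in the 5–15% range for raw
    prevalences below 1%.
    """

    control_fraction: float = 0.10
    unknown_keep_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("control_fraction", "unknown_keep_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def split_control(
    sentences: Sequence[Sentence], cfg: QualifyConfig
) -> tuple[list[Sentence], list[Sentence]]:
    """Reserve a uniform random control subset before any filtering.

    Returns (control, pool); their disjoint union is the input, both in
    input order.  Control size is round-half-up of fraction x n.
    """
    n = len(sentences)
    size = int(math.floor(cfg.control_fraction * n + 0.5))
    if cfg.control_fraction > 0 and cfg.control_fraction * n < 1:
        warnings.warn(
            f"control_fraction {cfg.control_fraction} of n={n} selects no sentences",
            stacklevel=2,
        )
        size = 0
    rng = np.random.default_rng(cfg.seed)
    idx = set(rng.choice(n, size=size, replace=False).tolist()) if size else set()
    control = [s for i, s in enumerate(sentences) if i in idx]
    pool = [s for i, s in enumerate(sentences) if i not in idx]
    return control, pool


def filter_by_preannotation(
    pool: Sequence[Sentence],
    decisions: Mapping[str, "RuleDecision | str"],
    cfg: QualifyConfig,
) -> list[Sentence]:
    """Keep all non-unknown-preannotated sentences; down-sample the rest.

    Every ``unknown``-preannotated sentence survives independently with
    probability ``unknown_keep_fraction`` (seeded, input order).  Decisions
    may be rule decisions or bare label strings (model preannotators).
    """
    for s in pool:
        if s.sent_id not in decisions:
            raise KeyError(f"no preannotation decision for sentence {s.sent_id!r}")

    def _label(d) -> str:
        return d.label if isinstance(d, RuleDecision) else d

    rng = np.random.default_rng(cfg.seed)
    kept: list[Sentence] = []
    for s in pool:
        if _label(decisions[s.sent_id]) != "unknown":
            kept.append(s)
        elif rng.random() < cfg.unknown_keep_fraction:
            kept.append(s)
    return kept


# ---------------------------------------------------------------------------
# Bias-assessment statistics
# ---------------------------------------------------------------------------


def _counts(labels) -> dict[str, int]:
    if isinstance(labels, Mapping):
        return {str(k): int(v) for k, v in labels.items()}
    out: dict[str, int] = {}
    for lab in labels:
        out[lab] = out.get(lab, 0) + 1
    return out


def status_proportions(labels) -> dict[str, float]:
    """Share of each relevant status among relevant samples, as a fraction.

    ``unknown`` is excluded from numerator and denominator.  With zero
    relevant samples every proportion is NaN (not applicable), never 0/0.
    """
    counts = _counts(labels)
    denom = sum(counts.get(s, 0) for s in RELEVANT_STATUSES)
    if denom == 0:
        return {s: float("nan") for s in RELEVANT_STATUSES}
    return {s: counts.get(s, 0) / denom for s in RELEVANT_STATUSES}


def prevalence(labels) -> float:
    """Density of relevant samples among all samples (``unknown`` included)."""
    counts = _counts(labels)
    relevant = sum(counts.get(s, 0) for s in RELEVANT_STATUSES)
    total = relevant + counts.get("unknown", 0)
    if total == 0:
        return float("nan")
    return relevant / total


@dataclass
class DistributionReport:
    """US vs PS status distributions per condition.

    ``table`` rows are present/absent/former proportions (in %, one decimal)
    and prevalence (in %, two decimals); columns are a (condition, subset)
    MultiIndex with subsets "US" and "PS".  NaN marks not-applicable cells.
    ``raw`` holds the unrounded fractions.
    """

    table: pd.DataFrame
    raw: pd.DataFrame


def distribution_report(
    us_labels: Mapping[str, Sequence[str] | Mapping[str, int]],
    ps_labels: Mapping[str, Sequence[str] | Mapping[str, int]],
) -> DistributionReport:
    """Compare status distributions between the unfiltered and filtered sets.

    Both arguments map condition name to a label multiset (sequence of
    labels or a label->count mapping).
    """
    conditions = list(us_labels)
    if set(ps_labels) != set(conditions):
        raise ValueError("us_labels and ps_labels must cover the same conditions")
    rows = list(RELEVANT_STATUSES) + ["prevalence"]
    cols = pd.MultiIndex.from_product([conditions, ["US", "PS"]])
    raw = pd.DataFrame(index=rows, columns=cols, dtype=float)
    for cond in conditions:
        for subset, labels in (("US", us_labels[cond]), ("PS", ps_labels[cond])):
            props = status_proportions(labels)
            for s in RELEVANT_STATUSES:
                raw.loc[s, (cond, subset)] = props[s]
            raw.loc["prevalence", (cond, subset)] = prevalence(labels)
    table = raw * 100.0
    table.loc[list(RELEVANT_STATUSES)] = table.loc[list(RELEVANT_STATUSES)].round(1)
    table.loc["prevalence"] = table.loc["prevalence"].round(2)
    return DistributionReport(table=table, raw=raw)
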