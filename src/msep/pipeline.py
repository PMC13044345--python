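"""Orchestration of the full iteration loop with reports and stopping rule.

One iteration runs: sentence segmentation -> preannotation (rules, or a
previous iteration's trained extractor) -> qualification (control subset +
unknown down-sampling) -> annotation ingestion with a kappa gate (a failed
gate triggers a term-driven revision sub-loop) -> deduplication ->
stratified cross-validation of the configured backend, compared against the
rule baseline on the same folds.  Iterations accumulate annotated data; the
preannotator for the next iteration is upgraded to the trained extractor
only when it beats the rules on the shared folds.  The loop stops when mean
macro F reaches the threshold or the iteration cap is hit.

Preannotations alone are never treated as gold: training labels always come
from the (possibly simulated) annotator records.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import (
    AnnotationRecord,
    CorrectionPlan,
    agreement_gate,
    annotation_time_summary,
    apply_corrections,
    cohen_kappa,
    select_for_revision,
)
from .corpus import Document, Sentence, segment_corpus
from .evaluate import (
    CrossValidationResult,
    breakdown_by_doctype,
    cross_validate,
    make_folds,
)
from .model import Extractor, LabeledDataset, LossSpec, RulesExtractor, train_linear
from .qualify import QualifyConfig, distribution_report, filter_by_preannotation, split_control
from .rules import RuleSet

__all__ = [
    "StopRule",
    "PipelineConfig",
    "IterationState",
    "PipelineError",
    "run_iteration",
    "should_stop",
    "render_reports",
]


class PipelineError(RuntimeError):
    """Raised when an iteration cannot proceed (e.g. failed kappa gate)."""


@dataclass
class StopRule:
    macro_f_threshold: float = 0.90
    max_iterations: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.macro_f_threshold <= 1.0:
            raise ValueError("macro_f_threshold must be in (0, 1]")


@dataclass
class PipelineConfig:
    condition: str
    rules: RuleSet
    qualify: QualifyConfig = field(default_factory=QualifyConfig)
    loss: LossSpec = field(default_factory=LossSpec)
    stop: StopRule = field(default_factory=StopRule)
    k: int = 3
    seed: int = 0
    kappa_threshold: float = 0.8
    double_annotation_fraction: float = 0.10
    min_per_class: int = 3
    backend: str = "linear"
    abbreviations: tuple[str, ...] = ()


@dataclass
class IterationState:
    """Cumulative pipeline state; the annotated dataset strictly grows."""

    iteration: int = 0
    items: list[tuple[Sentence, str]] = field(default_factory=list)
    reports: list[dict] = field(default_factory=list)
    preannotator: Extractor | None = None
    stop: bool = False


def should_stop(cv: CrossValidationResult, rule: StopRule, iteration: int) -> bool:
    """Stop iff mean macro F meets the threshold or the iteration cap is hit."""
    if cv.macro_f_mean >= rule.macro_f_threshold:
        return True
    if iteration >= rule.max_iterations:
        warnings.warn(
            f"iteration cap {rule.max_iterations} reached with mean macro F "
            f"{cv.macro_f_mean:.3f} below threshold {rule.macro_f_threshold}",
            stacklevel=2,
        )
        return True
    return False


def _kappa_subset(ids: Sequence[str], fraction: float, seed: int) -> list[str]:
    n = len(ids)
    size = max(2, int(round(fraction * n))) if n >= 2 else n
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(n, size=min(size, n), replace=False).tolist())
    return [ids[i] for i in idx]


def run_iteration(
    state: IterationState,
    documents: Sequence[Document],
    annotations: tuple[Sequence[AnnotationRecord], Sequence[AnnotationRecord]],
    config: PipelineConfig,
    correction_plan: CorrectionPlan | None = None,
) -> IterationState:
    """Execute one full pipeline iteration and return the grown state.

    ``annotations`` are the two annotator streams; they must cover the
    sentences the qualification step selects.  A failed kappa gate invokes
    the revision sub-loop when ``correction_plan`` is supplied (re-annotating
    the term-selected sentences to the first annotator's labels, archived
    with a guideline version tag) and halts otherwise.
    """
    it = state.iteration + 1
    log: dict = {"iteration": it, "condition": config.condition, "seed": config.seed}

    sentences = segment_corpus(documents, config.abbreviations)
    log["n_sentences"] = len(sentences)

    preannotator = state.preannotator or RulesExtractor(config.rules)
    decisions = preannotator.predict(sentences)
    log["preannotator"] = preannotator.backend_kind

    qcfg = dataclasses.replace(config.qualify, seed=config.qualify.seed + it)
    control, pool = split_control(sentences, qcfg)
    filtered = filter_by_preannotation(pool, decisions, qcfg)
    selected = control + filtered
    log["n_control"], log["n_filtered"] = len(control), len(filtered)

    rec_a, rec_b = annotations
    by_a = {r.sent_id: r for r in rec_a if r.condition == config.condition}
    by_b = {r.sent_id: r for r in rec_b if r.condition == config.condition}
    missing = [s.sent_id for s in selected if s.sent_id not in by_a]
    if missing:
        raise PipelineError(
            f"annotator A has no records for {len(missing)} selected sentences "
            f"(first: {missing[:3]})"
        )

    overlap_ids = [s.sent_id for s in selected if s.sent_id in by_b]
    subset = _kappa_subset(overlap_ids, config.double_annotation_fraction, config.seed + it)
    sub_a = [by_a[i] for i in subset]
    sub_b = [by_b[i] for i in subset]
    agreement = cohen_kappa(sub_a, sub_b, config.condition)
    log["kappa"] = agreement.kappa

    if not agreement_gate(agreement, config.kappa_threshold):
        if correction_plan is None:
            raise PipelineError(
                f"interannotator agreement kappa={agreement.kappa:.2f} below "
                f"threshold {config.kappa_threshold} and no correction plan "
                "supplied; analyze disagreements, list ambiguous terms and rerun"
            )
        by_sent = {s.sent_id: s for s in selected}
        revise_ids = select_for_revision(
            [by_sent[i] for i in overlap_ids], correction_plan
        )
        corrected = {i: by_a[i].label for i in revise_ids}
        new_b, archived = apply_corrections(
            [by_b[i] for i in overlap_ids], corrected, correction_plan.guideline_version
        )
        by_b = {r.sent_id: r for r in new_b}
        sub_b = [by_b[i] for i in subset]
        agreement = cohen_kappa(sub_a, sub_b, config.condition)
        log["kappa_after_correction"] = agreement.kappa
        log["n_corrected"] = len(archived)
        if not agreement_gate(agreement, config.kappa_threshold):
            raise PipelineError(
                f"agreement still below threshold after correction "
                f"(kappa={agreement.kappa:.2f}); extend the ambiguous-term list"
            )

    new_items = [(s, by_a[s.sent_id].label) for s in selected]
    items = state.items + new_items
    dataset = LabeledDataset(items, config.condition, config.min_per_class).deduplicated()
    log["n_annotated_total"] = len(dataset.items)
    log["status_counts"] = dataset.counts

    us_labels = {config.condition: [by_a[s.sent_id].label for s in control if s.sent_id in by_a]}
    ps_labels = {config.condition: [by_a[s.sent_id].label for s in filtered]}
    dist = distribution_report(us_labels, ps_labels)

    time_all, time_info = annotation_time_summary(
        [by_a[s.sent_id] for s in selected],
        {s.sent_id: by_a[s.sent_id].label for s in selected},
    )
    log["annotation_s_per_sentence"] = {"all": time_all, "informative": time_info}

    plan = make_folds(dataset, k=config.k, seed=config.seed)
    factories = {
        "rules": lambda train_items: RulesExtractor(config.rules),
        "linear": lambda train_items: train_linear(
            LabeledDataset(list(train_items), config.condition, config.min_per_class),
            config.loss,
        ),
    }
    cv_by_backend: dict[str, CrossValidationResult] = {}
    for name in ("rules", "linear") if config.backend == "linear" else ("rules",):
        cv_by_backend[name] = cross_validate(
            dataset, factories[name], k=config.k, seed=config.seed, plan=plan
        )
    cv = cv_by_backend[config.backend]
    comparison = pd.DataFrame.from_dict(
        {
            name: {"macro_f_mean": r.macro_f_mean, "macro_f_sd": r.macro_f_sd}
            for name, r in cv_by_backend.items()
        },
        orient="index",
    )

    # Preannotator upgrade gate: trained model replaces rules only if it
    # beats the rule baseline on the same folds.
    next_pre: Extractor = RulesExtractor(config.rules)
    if (
        config.backend == "linear"
        and cv_by_backend["linear"].macro_f_mean >= cv_by_backend["rules"].macro_f_mean
    ):
        next_pre = train_linear(dataset, config.loss)
    log["next_preannotator"] = next_pre.backend_kind

    report = {
        "log": log,
        "agreement": agreement,
        "distribution": dist,
        "cv": cv_by_backend,
        "comparison": comparison,
        "counts": dataset.counts,
        "n_new": len(new_items),
    }
    return IterationState(
        iteration=it,
        items=dataset.items,
        reports=state.reports + [report],
        preannotator=next_pre,
        stop=should_stop(cv, config.stop, it),
    )


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------


def _df_markdown(df: pd.DataFrame, float_fmt: str = "{:.3f}") -> str:
    def fmt(v) -> str:
        if isinstance(v, float):
            return "-" if np.isnan(v) else float_fmt.format(v)
        return str(v)

    df = df.copy()
    if isinstance(df.columns, pd.MultiIndex):
        df.columns = [" ".join(map(str, c)) for c in df.columns]
    header = [str(df.index.name or "")] + [str(c) for c in df.columns]
    lines = ["| " + " | ".join(header) + " |", "|" + "---|" * len(header)]
    for idx, row in df.iterrows():
        lines.append("| " + " | ".join([str(idx)] + [fmt(v) for v in row]) + " |")
    return "\n".join(lines) + "\n"


def _write(df: pd.DataFrame, out_dir: Path, stem: str) -> None:
    df.to_csv(out_dir / f"{stem}.csv")
    (out_dir / f"{stem}.md").write_text(_df_markdown(df), encoding="utf-8")


def _mean_per_status(cv: CrossValidationResult) -> pd.DataFrame:
    frames = [r.per_status for r in cv.reports]
    merged = pd.concat(frames, keys=range(len(frames)))
    mean = merged.groupby(level=1).mean()
    mean["balanced_accuracy"] = np.nan
    mean["macro_f"] = np.nan
    return mean


def render_reports(state: IterationState, out_dir: str | Path) -> list[Path]:
    """Materialize the standard report files (CSV + Markdown) from a state.

    Emits: per-iteration status counts, US/PS distribution, best-extractor
    per-status metrics, per-iteration cross-validation, document-type
    breakdown, and the extractor comparison.  Re-rendering the same state
    is byte-identical.
    """
    if not state.reports:
        raise PipelineError("state contains no iteration reports to render")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    last = state.reports[-1]
    condition = last["log"]["condition"]
    backend = [k for k in last["cv"] if k != "rules"] or ["rules"]
    best_name = max(last["cv"], key=lambda n: last["cv"][n].macro_f_mean)

    # 1. status counts per iteration
    counts_rows = {}
    for rep in state.reports:
        counts_rows[f"iter{rep['log']['iteration']}"] = {
            **rep["counts"],
            "total_annotated": sum(rep["counts"].values()),
            "newly_annotated": rep["n_new"],
        }
    _write(pd.DataFrame.from_dict(counts_rows, orient="index").fillna(0).astype(int),
           out, "status_counts")

    # 2. US/PS distribution (bias assessment)
    _write(last["distribution"].table, out, "us_ps_distribution")

    # 3. best extractor per-status metrics (fold means)
    best_cv = last["cv"][best_name]
    metrics = _mean_per_status(best_cv)
    metrics.loc["(aggregate)", "balanced_accuracy"] = float(
        np.mean([r.balanced_accuracy for r in best_cv.reports])
    )
    metrics.loc["(aggregate)", "macro_f"] = best_cv.macro_f_mean
    _write(metrics, out, "best_extractor_metrics")

    # 4. per-iteration cross-validation summary
    cv_rows = {}
    for rep in state.reports:
        for name, cvr in rep["cv"].items():
            row = {}
            for status in sorted(
                {s for r in cvr.reports for s in r.per_status.index}
            ):
                vals = [
                    r.per_status.loc[status, "f_score"]
                    for r in cvr.reports
                    if status in r.per_status.index
                ]
                row[f"{status}_f_mean"] = float(np.nanmean(vals))
            row["macro_f_mean"] = cvr.macro_f_mean
            row["macro_f_sd"] = cvr.macro_f_sd
            cv_rows[f"iter{rep['log']['iteration']}_{name}"] = row
    _write(pd.DataFrame.from_dict(cv_rows, orient="index"), out, "cv_by_iteration")

    # 5. document-type breakdown (fold mean and SD of F per status/type)
    sentences = [s for s, _ in state.items]
    per_fold = [
        breakdown_by_doctype(gold, pred, sentences)
        for gold, pred in best_cv.fold_predictions
    ]
    stacked = pd.concat(per_fold, keys=range(len(per_fold)))
    bd_mean = stacked.groupby(level=1).mean()
    bd_sd = stacked.groupby(level=1).std(ddof=1)
    bd = pd.concat({"mean_f": bd_mean, "sd": bd_sd}, axis=1)
    _write(bd, out, "doctype_breakdown")

    # 6. extractor comparison
    _write(last["comparison"], out, "extractor_comparison")

    summary = {
        "condition": condition,
        "iterations": state.iteration,
        "stop": state.stop,
        "best_backend": best_name,
        "configured_backend": backend[0],
        "logs": [rep["log"] for rep in state.reports],
    }
    (out / "run_log.json").write_text(
        json.dumps(summary, indent=2, ensure_ascii=False, default=str), encoding="utf-8"
    )
    stems = [
        "status_counts", "us_ps_distribution", "best_extractor_metrics",
        "cv_by_iteration", "doctype_breakdown", "extractor_comparison",
    ]
    return [out / f"{s}.csv" for s in stems]
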