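# Methods

## Task and model

The unit of analysis is the sentence. For each targeted medical condition a
sentence carries exactly one status: `present` (confirmed), `absent`
(negated), `former` (the condition ceased — declared only for conditions
where cessation is meaningful, smoking in the shipped configuration), or
`unknown` (no usable information). Statuses are mutually exclusive per
(sentence, condition); multi-condition sentences receive one independent
decision per condition.

The pipeline's premise is an extreme sparsity/imbalance regime: in an
unfiltered hospital corpus, informative sentences for a single condition are
on the order of 0.1–0.8% of all sentences, and `absent` is typically much
rarer than `present`. Every design choice below follows from making
annotation and training workable in that regime.

## Sentence segmentation

Documents are split by a deterministic rule: a newline or one of `. ! ?`
ends a sentence, except periods inside a protected abbreviation token
("M.", "Dr.", "cf." — shipped as an editable list, matched at word start,
case-insensitively). Spans are whitespace-trimmed, 0-based half-open, and
`document.text[start:end] == sentence.text` holds exactly; spans are
disjoint, ordered, and jointly cover all non-whitespace characters.
Sentence ids are `doc_id + ":" + span_start`, stable across re-runs.

Known limitation: the rule is intentionally literal, so a period inside a
decimal number ("3.5") splits unless protected. A statistical segmenter can
be substituted by producing `Sentence` objects through any other means —
all downstream stages consume the `Sentence` container, not the splitter.

## Rule-based classification

A `RuleSet` holds per-condition keyword patterns (case-insensitive regular
expressions) and four cue lexica: negation, family context, cessation,
relapse. The decision procedure:

1. No keyword match → `unknown`.
2. Otherwise the scope is the **clause** containing the first keyword
   occurrence, where clauses are maximal runs between the delimiters
   `, ; :` and the coordinators `mais`, `et` (word-bounded). Clause scoping
   is the simplest auditable rule that handles the common failure where a
   trailing negation ("Tabac : non") belongs to a different clause than the
   keyword.
3. Cue precedence inside the clause:
   `family > relapse > cessation > negation > bare keyword`.
   - family cue → `present` if the condition is itself familial (family
     history of cancer), else `unknown` (the relative has it, not the
     patient);
   - relapse cue → `present` (overrides cessation: "reprise … malgré un
     sevrage" describes an active smoker);
   - cessation cue → `former` where declared, else `absent`;
   - negation cue counts only when it **precedes** the keyword in the
     clause → `absent`;
   - otherwise `present`.

Matching is case-insensitive but diacritic-sensitive (stripping accents in
French clinical text invites false cue hits, e.g. `sevré` vs `sevre`). The
shipped lexica for the six demonstration conditions (smoking, diabetes,
hypertension, heart failure, COPD, family history of cancer) are
reconstructions intended for testing and as starting points, not validated
clinical resources.

Known limitation of the precedence order: for familial conditions a negated
family mention ("pas d'antécédent familial de cancer") still classifies
`present`, because family outranks negation. The shipped generator does not
produce that pattern (its familial condition has essentially no `absent`
samples, matching the sparsity observed for that status in practice), but
users targeting negated family history should adapt the rule set.

## Data qualification

Before any preannotation-based decision, a control fraction (default 0.10,
size round-half-up, drawn per-sentence, uniformly, seeded) is reserved —
the unfiltered subset (US) used to audit selection bias. From the remaining
pool, sentences preannotated `unknown` survive independently with
probability `unknown_keep_fraction`; all non-`unknown` preannotations are
kept. The default keep fraction 0.05 puts the expected post-filter
prevalence `p / (p + 0.05(1−p))` in the 5–15% band for raw prevalences
below 1% (≈13% at p = 0.75%), a ~17× densification.

The bias audit computes, per condition and per subset (US vs the filtered
set PS): the proportion of each relevant status among relevant samples
(`unknown` excluded from numerator and denominator) and the prevalence of
relevant samples (`unknown` in the denominator). Zero-relevant cells are
not-applicable (NaN), never 0/0. Report tables round proportions to 0.1%
and prevalence to 0.01%.

## Agreement and correction

Cohen's kappa is computed on the doubly-annotated overlap (default 10% of a
batch, seeded): `κ = (P_o − P_e)/(1 − P_e)` with `P_e` from the two
annotators' marginals. Degenerate convention: when `P_e = 1` (both
annotators constant on the same label) κ is defined as 1 if `P_o = 1`, else
0, since the formula is undefined there. The gate passes iff κ ≥ threshold
(default 0.8, boundary inclusive).

On failure, disagreements are listed, an ambiguous-term list selects
sentences by case-insensitive normalized substring containment, and
corrections replace the superseded records, which are archived with a
guideline-version tag on the annotator id. Annotation-time accounting
reports mean seconds per sentence overall and restricted to informative
sentences (dismissing an uninformative sentence is much faster than
labeling an informative one, so the two means differ by design).

## Training objective and linear backend

Class weights follow `w_c = N / (C · N_c)` over the classes with at least
`min_per_class` (default 3) samples; rarer statuses are excluded from
training and evaluation rather than crashing cross-validation, which is the
standard handling for statuses with only a handful of samples. The identity
`N_c · w_c = N / C` holds for every class.

The self-contained backend is multinomial logistic regression over hashed
word-unigram and character 3–5-gram counts (default dimension 2^18,
collisions accepted; rows L2-normalized). It is a deliberately transparent,
dependency-free stand-in at the same interface where a fine-tuned encoder
or a prompted LLM would sit in production; those backends are exposed as
prediction-file stubs so the comparison harness treats all extractors
uniformly.

Optimization: full-batch gradient descent on the weight-normalized
objective `Σ w_i CE_i / Σ w_i` plus L2 (default 1e-4), initial step 2.0,
halved whenever a step would increase the loss, capped at 500 iterations,
stopping when the decrease falls below 1e-7. Consequences: training loss is
non-increasing, runs are bitwise deterministic (zero initialization, no
stochastic minibatching), and scaling all class weights by a constant
leaves the fitted model bitwise identical. The raw (unnormalized) weighted
cross-entropy is available separately; true-class probabilities of zero are
clamped at 1e-12 with a warning.

## Evaluation

Identical sentences (lowercased, whitespace-collapsed) are removed before
fold construction so no duplicated text can sit in both a training and a
validation fold. Stratified folds are dealt round-robin within class after
a seeded shuffle, with the starting fold rotating across classes; this
guarantees fold sizes differ by at most one both per class and overall.
`k` equal to the dataset size is accepted as leave-one-out. Folds are
sentence-stratified, not patient-partitioned; the patient-overlap audit
quantifies how many validation sentences share a patient with the training
folds.

Metrics are one-vs-rest per status: precision, recall, specificity,
F-score; aggregates (balanced accuracy, macro F) average over the
**evaluated statuses** — by default the classes with gold support in the
validation fold — and undefined ratios (0/0) are excluded from aggregates
with a flag rather than coerced to 0. The same convention marks
unsupported (status × document-type) cells "–" in the breakdown tables.
Fold dispersion is the sample standard deviation (ddof 1). The optional
extractor comparison runs all backends on one shared fold plan and offers a
two-sided paired t test on per-fold macro F (k−1 df).

## Synthetic corpus generator

The generator emulates the statistical structure the pipeline assumes —
not clinical language. Each sentence slot is either a planted (condition,
status) event, drawn from configured per-condition prevalences, or filler;
text comes from status-specific French templates with randomized numeric
slots (years, doses, dates) so duplicates arise only when injected
deliberately. The default prevalences put each condition's informative mass
in the sub-percent range with `absent ≪ present`, `former` only for
smoking, and essentially no `absent` for COPD / familial cancer; documents
draw a type from a skewed mix (nursing procedures 41%, medical reports
23%, …) and a patient from a finite pool. Duplicate injection re-emits
earlier text under fresh ids (possibly other patients), exercising both
deduplication and the patient-overlap audit. Planted-count bookkeeping
equals realized gold counts exactly.

Two properties tie the generator to the rule module: at cue noise 0 every
template is classified correctly by the shipped lexica (clean-cue
identifiability, macro F = 1.0), and with probability `cue_noise` an
informative sentence instead uses a paraphrase whose cue (or keyword) lies
outside the lexica, so rule accuracy degrades with noise while a trained
classifier can still learn the paraphrases.

What passing tests on this generator do **not** show: robustness to real
clinical language (typos, telegraphic style, hedging, section headers,
table fragments), to lexicon gaps beyond the scripted paraphrases, or to
label noise in gold annotations. The template bank is finite, so a trained
model can saturate (macro F = 1.0) with a few hundred annotated sentences;
real corpora saturate far later. The data-doubling experiment is therefore
run in a deliberately low-data regime (half-size training sets of ~50
sentences, 40% paraphrase noise, 4 statuses) where template coverage is
incomplete and additional annotation genuinely helps — the scaled-down
analogue of an underperforming first iteration. An English template bank
is included for portability demonstrations only; the shipped lexica are
French, so the rule-recovery guarantee applies to the French bank.

The annotator simulator makes annotator A reproduce gold and annotator B
flip each label to a uniformly random other label with a configured rate
(so observed agreement ≈ 1 − rate); durations are lognormal with
`μ = ln(mean) − σ²/2` (σ = 0.4), means 1.5 s for `unknown` and 3.0 s for
informative sentences.

## Iteration loop

Each iteration segments, preannotates (rules first; later iterations may
use the previous iteration's trained extractor, but only if it beat the
rule baseline on the shared folds), qualifies, ingests annotations behind
the kappa gate, deduplicates the accumulated dataset, cross-validates the
configured backend against the rules, and stops when mean macro F reaches
the threshold (default 0.90) or the iteration cap is hit. Preannotations
are never used as training labels — only (possibly simulated) annotator
records are. Reports (status counts per iteration, US/PS distribution,
best-extractor metrics, per-iteration cross-validation, document-type
breakdown, extractor comparison) render deterministically to CSV and
Markdown; re-rendering a state is byte-identical.

## Problem sizes

The shipped tests and the acceptance script use corpora of 10,000 sentences
for the densification experiments (10 seeds), 2,000 sentences for extractor
recovery, and 96-sentence training corpora (10 seeds) for the data-doubling
property, with hashing dimensions 2^14–2^16; these sizes were chosen so
each experiment's conclusion is stable across seeds at desk scale.
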