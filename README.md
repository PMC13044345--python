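# msep — medical status extraction from clinical text

`msep` builds per-condition patient-status extractors from unstructured
clinical documents by **sentence classification**: every sentence is assigned
one status per medical condition — `present`, `absent`, `former` (for
conditions that can cease, such as smoking) or `unknown` (no usable
information). It is aimed at clinical-NLP teams who need to construct local
extraction models from a hospital data warehouse, where informative
sentences are extremely sparse (well under 1% of sentences before filtering)
and annotation time is the binding constraint.

The package implements the full annotation-efficiency pipeline:

1. **Segmentation** — deterministic rule splitting of documents into
   sentences with exact character spans and provenance (document, patient,
   document type).
2. **Rule-based preannotation** — per-condition keyword patterns with
   clause-scoped cue lexica and precedence
   `family > relapse > cessation > negation > bare keyword`, e.g.
   "reprise récente malgré un sevrage" → `present` (relapse overrides
   cessation).
3. **Data qualification** — an unbiased control subset is reserved before
   filtering; sentences preannotated `unknown` are then down-sampled to
   raise informative density. Selection bias is audited per status with

   ```
   proportion(s) = c(s) / c(present, absent, former)
   prevalence    = c(present, absent, former) / c(all statuses)
   ```

4. **Annotation management** — two-annotator records, Cohen's kappa
   `κ = (P_o − P_e) / (1 − P_e)` gated at 0.8, disagreement extraction, and
   term-driven correction rounds with an audit trail.
5. **Class-weighted training** — weighted cross-entropy
   `L = −Σ_i w_i log p(y_i|x_i)` with `w_i = N / (C · N_{y_i})`, so each
   class contributes equal aggregate mass. A self-contained multinomial
   linear backend (hashed word + character 3–5-gram features, deterministic
   full-batch gradient descent) trains with this objective; external
   fine-tuned or prompted extractors plug in through a prediction-file stub.
6. **Evaluation** — deduplicated stratified k-fold cross-validation;
   per-status precision / recall / specificity / F; balanced accuracy
   `(1/C) Σ_c [(TP_c/(TP_c+FN_c) + TN_c/(TN_c+FP_c))/2]` and macro F
   `(1/C) Σ_c F1(c)` over the evaluated statuses; document-type breakdowns
   and a patient-overlap leakage audit.
7. **Iteration loop** — accumulate annotations, upgrade the preannotator to
   the trained extractor when it beats the rules, stop at macro F ≥ 0.90 or
   an iteration cap.

A synthetic clinical-corpus generator (`msep.synth`) reproduces the
statistical structure of a hospital corpus — sparse informative sentences,
class imbalance, skewed document-type mix, duplicates, patient grouping —
with exact gold labels, so every stage is testable without any private data.

## Worked example

```python
from msep import (QualifyConfig, SynthConfig, cross_validate, generate,
                  labeled_dataset, preannotate, simulate_annotators)
from msep.model import LabeledDataset, LossSpec, RulesExtractor, train_linear
from msep.rules import builtin_ruleset

# A synthetic corpus at a dense informative regime, 10% paraphrase noise
corpus = generate(SynthConfig(
    n_documents=250, sentences_per_document=8, cue_noise=0.10, seed=11,
    conditions={"diabetes": {"present": 0.18, "absent": 0.12}},
))
ds = labeled_dataset(corpus, "diabetes").deduplicated()
print(ds.counts)

cv_rules = cross_validate(
    ds, lambda items: RulesExtractor(builtin_ruleset("diabetes")), k=3, seed=1)
cv_linear = cross_validate(
    ds, lambda items: train_linear(
        LabeledDataset(list(items), "diabetes"), LossSpec(hash_dim=2**16)),
    k=3, seed=1)
print(f"rules  macro F {cv_rules.macro_f_mean:.3f} (sd {cv_rules.macro_f_sd:.3f})")
print(f"linear macro F {cv_linear.macro_f_mean:.3f} (sd {cv_linear.macro_f_sd:.3f})")
```

prints

```
{'present': 131, 'absent': 172, 'unknown': 613}
rules  macro F 0.960 (sd 0.026)
linear macro F 1.000 (sd 0.000)
```

The rule extractor misses the 10% of informative sentences whose cue was
paraphrased outside its lexicon, while the trained linear backend learns the
paraphrases from the annotated data — the qualitative pattern that motivates
training a classifier once enough annotations exist.

The same stages are scriptable from the shell:

```bash
msep synth --seed 3 --out-dir corpus
msep segment --corpus corpus/documents.jsonl --out sentences.jsonl
msep preannotate --corpus sentences.jsonl --condition smoking --out pre.jsonl
msep qualify --sentences sentences.jsonl --decisions pre.jsonl --seed 1 --out-dir qual
msep crossval --data labeled.jsonl --condition diabetes --backend linear
```

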