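# thrombotext

Classification of French CT angiography / venography (CTA/CTV) radiology
reports for three document-level diagnoses: **pulmonary embolism (PE)**,
**deep-vein thrombosis (DVT)** and **clinically relevant incidental
findings** ("incidentalomas" — nodules, masses, enlarged lymph nodes that
need follow-up but are unrelated to the exam's indication).

The package is aimed at clinical-NLP practitioners and epidemiology teams
who need document-level thromboembolic status from free-text imaging
reports — for e-cohort construction, trial eligibility screening or
surveillance — and who want every stage of such a pipeline available as
inspectable, testable code.

## The method

Reports are modelled as structured documents (identification, indication,
protocol, results, conclusion sections) carrying a concept-level
annotation layer:

* **concepts** — thromboembolic conditions (`ThromboPat`), clinically
  relevant findings (`K`), post-partum status (`PP`), anatomy (`Anatomy`),
  diagnostic procedures (`Exam`);
* **modalities** on conditions — `Positive`, `Negative`, `Hypothetical`,
  plus `Known` and `Incidental` for findings, separating "embolie
  pulmonaire" asserted from the same words negated ("pas d'embolie
  pulmonaire") or merely suspected;
* **relations** — `Location_of` (condition → anatomy) and `Reveals`
  (exam → condition).

Each report *d* becomes a binary feature vector x(d): text unigrams /
bigrams (`tok:`, `big:`), concept features (`con:type:surface`), modality
features (`mod:modality:type:surface`) and relation features
(`rel:type:type₁:type₂`), optionally typed by section or restricted to
the *critical sections* (results + conclusion). Two from-scratch
classifiers decide each binary task:

* **Bernoulli Naïve Bayes** with add-α smoothing:
  P(y|x) ∝ P(y) ∏_f P(x_f|y), x_f ∈ {0,1};
* **Maximum entropy** (binary logistic regression),
  maximizing ∑ᵢ log p(yᵢ|xᵢ; w, b) − l₁‖w‖₁ − (l₂/2)‖w‖² by monotone
  proximal gradient descent.

Class imbalance (≈73% of reports are negative for both PE and DVT) is
handled by **positive replication**: the held-out test set stays
imbalanced, while training positives are replicated (×3 for PE/DVT, ×5
for incidental findings) and negatives are subsampled to the replicated
count. Evaluation is per-task precision / recall / F-measure;
inter-annotator agreement is scored as F with exact (identical span and
type) or inexact (overlapping span, same type) entity matching.

Around the classifiers sit the rest of the pipeline: a two-list keyword
query for corpus selection (a report is kept iff it contains ≥1 CTA term
and ≥1 CTV term after case/diacritic folding) with its audit; rule-based
section splitting; a longest-match lexicon matcher for concept
pre-annotation; Brat standoff (.ann) reading and writing; and a
synthetic-corpus generator that produces sectioned French-style reports
with gold annotations and labels at the study prevalences, so the whole
chain is testable without any clinical data.

## Worked example

Run the end-to-end pipeline on a generated corpus (600 reports, MaxEnt,
text + annotation features):

```bash
thrombotext run --seed 1 --out-dir demo_run
```

which prints (abridged):

```json
{
  "config_hash": "6799c4d2f764",
  "seed": 1,
  "n_selected": 600,
  "tasks": {
    "pe":            {"tp": 26, "fp": 0, "fn": 0, "tn": 74, "f_measure": 1.0},
    "dvt":           {"tp": 25, "fp": 0, "fn": 0, "tn": 75, "f_measure": 1.0},
    "pe_dvt":        {"tp": 34, "fp": 0, "fn": 0, "tn": 66, "f_measure": 1.0},
    "incidentaloma": {"tp": 18, "fp": 0, "fn": 1, "tn": 81, "f_measure": 0.973}
  },
  "iaa": {"exact": 1.0, "inexact": 1.0}
}
```

Reading: all 600 generated reports name both exam types, so the keyword
query selects them all; on the 100-report imbalanced test set the MaxEnt
classifier with annotation features recovers PE and DVT perfectly and
misses one incidental finding (recall 18/19); the lexicon matcher's
pre-annotations agree perfectly with the gold annotations because this
corpus was generated without spelling noise. Artifacts (`corpus/`,
`labels.tsv`, `selected.txt`, `pre_ann/`, `evaluation.tsv`, `iaa.tsv`,
`summary.json`) land in `demo_run/`, each stamped with the config hash
and seed; rerunning the same configuration reproduces them byte for
byte.

The stages are also available individually (`thrombotext generate`,
`select`, `annotate`, `train`, `predict`, `evaluate`, `iaa`) and as a
library (`thrombotext.query`, `.lexicon`, `.features`, `.classifiers`,
`.experiment`, ...).

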