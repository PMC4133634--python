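# Methods

This note documents the modelling and engineering choices behind
`thrombotext`: what each stage computes, the parameters that matter, what
the synthetic corpus does and does not emulate, and the numerical
details a maintainer would otherwise have to reverse-engineer.

## Data model

A report is UTF-8 text with ordered, non-overlapping sections typed as
IDENTIFICATION / INDICATION / PROTOCOL / RESULTS / CONCLUSION / UNKNOWN.
All offsets are 0-based, half-open, counted in Unicode code points; this
convention is applied uniformly to sections, tokens, sentence spans and
annotations, so every unit's surface equals the source substring.

The annotation scheme has five concept types (`ThromboPat`, `K`, `PP`,
`Anatomy`, `Exam`), five modalities and two relations. Scheme
constraints are enforced at validation time: assertion modalities
(Positive/Negative/Hypothetical) attach only to `ThromboPat` or `K`;
Known/Incidental only to `K`; `Location_of` links a condition to an
`Anatomy` concept; `Reveals` links an `Exam` to a condition. Brat
standoff files are the interchange format. Both attribute dialects
(`A1␉Negative T1` and `A1␉Modality T1 Negative`) parse; the binary
dialect is written. Discontinuous spans are rejected — the scheme uses
contiguous mentions only, and silently fragmenting them would corrupt
offset arithmetic downstream.

## Corpus selection query

`QuerySpec` keeps two term lists (CTA-related, CTV-related) and selects
a report iff its text contains at least one term from each list, by
substring containment on case-folded, diacritic-folded,
whitespace-collapsed text. Normalization is explicit and configurable
because spelling and abbreviation variants ("phléboscan" /
"phlebo-scan") are the dominant cause of missed reports in this kind of
keyword retrieval. Only the published example terms are bundled; full
lists are site-specific configuration (plain text, one term per line).
The audit computes TP/FP/FN/TN against relevance judgments with the
convention P = R = F = 0 when a denominator is 0.

## Preprocessing

*Tokenizer*: maximal word runs (letters/digits, internal hyphens kept —
"phlebo-scan" is one token) plus single punctuation marks; a French
apostrophe clitic ("d'", "l'") ends its token only when glued to a
following word, so "pas d'embolie" → `pas · d' · embolie`. *Sentence
splitter*: boundaries at sentence-final punctuation followed by
whitespace and an uppercase/digit/newline, with a small abbreviation
stoplist ("M.", "Dr", "cf", ...). *Section splitter*: a line is a header
when it is short (≤4 words), optionally colon-terminated, and its folded
title appears in the synonym table (e.g. "Technique"/"Protocole" →
PROTOCOL, "Résultat(s)" → RESULTS); text before the first header is
IDENTIFICATION, colon-terminated unknown titles open UNKNOWN sections.
The synonym table is configuration, not a reconstruction of any
hospital's exact patterns; section spans exclude their header line
(header kept as metadata) and are trimmed to their non-whitespace
extent, which makes sectioning stable under padding.

## Lexicon matching

The matcher is a left-to-right, longest-match-first dictionary scan
anchored at token boundaries over folded text. Token anchoring prevents
abbreviations from firing inside words ("EP" never matches within
"hépatique"). Matches cannot overlap; the scan resumes after each
match. Duplicate lexicon rows collapse; one term mapping to two concept
types is a load error (naming the term), since silent precedence would
make annotations depend on file order. When the same term+type arrives
from several provenances, the clinically-sourced tag wins — an arbitrary
but deterministic, documented choice. The bundled lexicon is a ~60-term
demonstration covering all five types; the original terminology
(1242 terms: 674 anatomy, 278 thrombopathology, 207 finding terms, the
remainder exam/post-partum vocabulary) is not redistributable, and user
lexicons in the same TSV format are accepted at any size.

## Features

Binary presence encoding throughout: repeating a token or concept does
not change a vector. Namespaces: `tok:`, `big:`, `con:type:surface`,
`mod:modality:type:surface`, `rel:rtype:type1:type2`, with an optional
`sec:SECTION|` prefix. Design choices:

* modality features bind modality to concept type **and** surface, so an
  asserted and a negated mention of the same condition are distinct
  features — the property that makes the annotation layer informative at
  all (negated mentions outnumber asserted ones in this domain);
* relation features encode argument *types* by default (surfaces behind
  `relation_surfaces=True`), keeping the feature space small;
* section typing prefixes both text and annotation features (one flag),
  and is mutually exclusive with the critical-section restriction
  (results + conclusion only), which filters by the anchor offset of
  each feature;
* the "frequent and non-discriminating" stopword filter is
  operationalized as document-frequency bounds computed on the training
  corpus: drop text n-grams with df > 0.8·N or df < 2. No fixed list is
  shipped; the bounds are recomputed per training corpus and exposed as
  `max_df` / `min_df`.

The feature index is fitted on training reports, sorted, and frozen;
test-only features are dropped. Matrices serialize to a sparse text
format and export to ARFF for external toolkits.

## Classifiers

*Naïve Bayes* uses the Bernoulli event model — absent features
contribute log(1−p) — because the encoding is binary; a multinomial
model would conflate presence with frequency. Smoothing is add-α on
presence and absence counts, α = 1 by default, p̂ = (c + α)/(n_c + 2α),
strictly inside (0,1). The prior is the training class frequency, i.e.
0.5 after balancing. Prediction accumulates in log space over **all**
features; ties break towards the positive class (in screening, a missed
positive costs more than a spurious one).

*MaxEnt* is binary logistic regression with an elastic-net penalty
(defaults l₁ = 0, l₂ = 1; the bias is unpenalized). The optimizer is
deterministic monotone proximal gradient descent from zero
initialization with backtracking line search; the weight block and the
bias use separate step sizes derived from their curvature bounds
(0.25·‖X‖₁‖X‖∞ + l₂ and 0.25·n), because a large l₂ would otherwise
freeze the unpenalized bias. Convergence: objective change < tol
(1e-8) or `max_iter` (2000). The accepted-step objective sequence is
stored on the model and is non-increasing by construction. A support
vector machine is deliberately not provided; in this setting it brings
no advantage over the MaxEnt model.

Both models serialize to a plain-text feature→parameter format.
scikit-learn's `BernoulliNB` and `LogisticRegression` are used in the
test suite as independent references (decision agreement ≥ 99%), never
at runtime.

## Imbalance handling and evaluation

`make_split` first draws the test set (default 100 reports, uniformly
without replacement — the same test ids for every task at a given
seed), then replicates remaining positives (×3 for PE/DVT/PE-or-DVT,
×5 for incidental findings) and subsamples negatives **without**
replacement down to the replicated-positive count; sampling without
replacement preserves negative-side diversity, and equal class sizes
are the target of the adjustment. If negatives run short, all are used
with a warning. The ×5-then-adjust scheme applies to incidental
findings identically; `adjust_negatives=False` disables the
subsampling. Cross-validation is intentionally absent: replicated
positives would leak across folds. Evaluation is per-task TP/FP/FN/TN
with P, R, F = 2PR/(P+R), zero-denominator cases defined as 0.

## Inter-annotator agreement

Entities pair greedily one-to-one in start-offset order under the match
criterion (exact: identical span and type; inexact: overlapping span,
identical type); a relation matches when its type is identical and both
arguments are paired entities. Annotator A is the reference (recall
denominator); per-category counts are micro-averaged for the overall
score. Greedy offset-ordered pairing is deterministic and symmetric on
realistic annotation geometries; pathological overlap webs where greedy
pairing is not maximum-cardinality are possible in principle but do not
occur for contiguous clinical mentions.

## Synthetic corpus

The generator emulates the *structure* of CTA/CTV reports, not their
prose: five canonical sections; an indication naming the clinical
suspicion (hence a Hypothetical thromboembolic mention in every
report); a protocol naming both exam types; results stating one
pulmonary and one venous finding (asserted or negated/hypothetical,
with `Location_of` anatomy), optional incidental or known/negated
finding distractors; a conclusion restating the thromboembolic findings
— but **not** incidental ones, which appear in results only, matching
how radiologists actually report them. Labels are drawn from the joint
CTA/CTV outcome distribution observed on the 573-report study corpus
(12.9 / 9.1 / 5.2 / 72.8%, incidentaloma margin 16.2%); these defaults
are the study conditions, not tuning knobs. One seeded RNG stream
drives everything; documents are generated in index order, so corpora
are byte-reproducible.

Positive and negative realizations deliberately share their cue
vocabulary: assertion verbs ("présence", "mise en évidence",
"visualisation") and negation cues ("pas de", "absence de", "sans",
"doute sur", "ne permet pas d'exclure") also occur in neutral filler
observations, so no single token betrays a label and plain-text
baselines remain honest. The cue inventory defines the synthetic ground
truth only — the real annotation task assigned modalities manually and
published no cue list. Spelling noise (`noise` ∈ [0,1], default 0)
perturbs each lexical slot with one character edit or a listed
abbreviation variant, degrading lexicon-matcher recall monotonically
while leaving gold annotations intact.

What passing tests on this corpus shows: the pipeline's plumbing is
correct end to end (offsets, scheme constraints, balancing, metric
arithmetic), the classifiers recover a clean modality signal, and the
qualitative feature-set ordering (annotations > plain text, MaxEnt ≥
Naïve Bayes) emerges under the study's class distribution. What it does
not show: performance on real clinical French, whose lexical variety,
typos, telegraphic syntax and layout irregularities are far beyond these
templates; published scores on the real corpus are not reproducible
from synthetic data, and no claim of that kind is made.

## Numerical and degenerate-input conventions

Empty text tokenizes to an empty list; a report without headers is one
IDENTIFICATION section; an empty lexicon matches nothing (load warns);
single-class training raises; metric denominators of zero yield 0;
Naïve Bayes posteriors are normalized in log space (max-subtraction)
and match a brute-force Bayes computation to 1e-12; the MaxEnt
optimizer's solution matches a refined grid search of the penalized
objective to 1e-3 on small problems. The experiment-scale defaults used
by the acceptance script — 600-report corpora, 100-report test sets,
1000 reports for prevalence concentration, 10 doubly-annotated reports
for agreement — keep every check well inside interactive runtimes while
leaving enough positives per task for stable F estimates.

## Known limitations

* The generator's French is templated; models trained on it do not
  transfer to real reports.
* Modality and relation detection are not provided as validated
  automatic components: gold annotations (or the cue-based synthetic
  ground truth) stand in for the manual annotation step. Automatic
  assertion classification would be the natural next component.
* The bundled lexicon is a demonstration; recall on real text is a
  direct function of user-supplied lexicon coverage.
* The section-header table and sentence rules are declared conventions;
  site-specific layouts need configuration.
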