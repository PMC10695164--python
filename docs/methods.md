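# Methods

This note documents the models, rules and numerical choices behind `szrec`:
what each stage computes, the assumptions it makes, the parameters that
matter, and what the synthetic cohorts do and do not emulate.

## Temporal conventions

Dates are integer day offsets from a fixed epoch (2010-01-01) internally and
ISO-8601 strings on disk. All clinical windows use fixed-day arithmetic:
1 week = 7 days, 1 year = 365 days, 2 years = 730 days, and "before the age
of 21 years" means `index_date < birth_date + 21 × 365`. Calendar-aware
arithmetic (leap days, month lengths) would change window boundaries by at
most a day or two per decade of age at the cost of platform-dependent
subtleties; fixed-day windows are exactly reproducible.

## Cohort inclusion

The index event is the *earliest* encounter carrying any broad seizure-like
code (ICD-9 345.\*, 780.3\*; ICD-10 G40.\*, R56.\*), accepted only if it
falls before the 21st birthday. The age gate applies to that earliest
encounter: a patient whose first seizure-like code appears at 22 has no
index event at all, rather than indexing on a later encounter.

Three criteria gate inclusion. (1) *Prior contact*: any encounter at least
365 days pre-index — any reason, any codes — or, for infants under 365 days
old at index, a **non**-seizure-like encounter at least 7 days pre-index
(the "for other purposes" reading: an infant referred for previous seizures
should not qualify through a seizure visit). (2) A qualifying index
encounter. (3) *Follow-up*: any encounter at least 730 days post-index. In
claims modality the contact criteria are evaluated on closed coverage
intervals instead: an interval containing `index − 365` (or `index − 7` for
infants, where the non-seizure qualifier cannot be checked) and coverage
reaching `index + 730`. Exclusion reasons are reported with priority
no-index-event → prior-contact → follow-up.

Code matching is prefix-based on dot-stripped, uppercased codes, each prefix
tagged with its dialect, so "345.\*\*" matches any ICD-9 code starting
"345" and never an ICD-10 code. The shipped registry is a documented
default; study-grade code lists drop in via YAML.

## Composite outcome

All seven measures observe only events in `(index + 7 d, index + 730 d]`.
The 7-day blanking generalizes the principle that the earliest a patient can
be considered recurrent is one week after the index event; events on or
before the blanking boundary never contribute to any criterion, which also
makes every criterion monotone in the post-index event set.

- **ASM therapy**: a lexicon medication record co-occurring on the same
  calendar day with an encounter carrying an epilepsy-specific diagnosis
  (ICD-9 345.\* / ICD-10 G40.\*; convulsion families 780.\*/R56.\* are
  excluded by construction). Same-day rather than same-encounter linkage,
  because claims data lack reliable encounter ids. This filters ASMs
  prescribed for other indications (gabapentin for neuropathic pain).
  `require_adjunctive_only` restricts to adjunctive-flagged agents.
- **Status epilepticus**: an SE code in the window, required to be in
  primary/admitting position itself or accompanied by an epilepsy-specific
  primary/admitting code — filtering incidental mentions.
- **Procedures**: an epilepsy-related procedure whose same-day encounter has
  an epilepsy-specific primary/admitting diagnosis, plus a confirmatory
  epilepsy-specific diagnosis ≥ 7 days after the procedure (guards against
  procedures miscoded as recurrence). The confirmation may fall after the
  outcome window; bounding it at 730 days would make the criterion
  non-monotone at the window edge.
- **Utilisation**: distinct encounter *days* (not encounters), seizure-
  related or all-cause, against thresholds of 2 and 4 distinct days. The
  thresholds are artifact defaults exposed in `OutcomeConfig`; "seizure-
  related" here is the broader union of epilepsy-specific and convulsion
  codes, since utilisation tracking and the strict outcome coding serve
  different purposes. The all-cause criterion can be disabled (it is
  arguably descriptive rather than an outcome); disabled, its field reports
  False so the composite stays the OR of the seven fields.
- **Inpatient admissions / diagnostic testing**: threshold counts of
  seizure-related inpatient encounters and of EEG/imaging orders
  co-occurring with a seizure-related diagnosis.

## Structured features and selection

Counts of every code in `[index − 365 d, index]` (the index day included),
namespaced `dx:`/`rx:`/`px:`, squashed by `min(ln(count + 1), 1)`. The
natural log makes the clip engage at two occurrences, giving a three-level
signal {0, ln 2, 1}: the first occurrence of a code is most informative and
repeat billing is discounted. An optional code→group mapping (e.g. an
ICD→PheCode table) plugs in at vocabulary construction; the default identity
mapping keeps the artifact self-contained.

Selection is fitted on training folds only. The prevalence scheme keeps
features nonzero in ≥ 1% of training rows; the χ² scheme keeps the top 500
features by the one-degree-of-freedom statistic on presence/absence versus
the label, computed from the 2×2 table without continuity correction, ties
broken by vocabulary order for determinism.

## Note pipeline

Tokenization is whitespace splitting — the chunk arithmetic is the object of
interest, not a subword vocabulary. Notes over `max_tokens` = 4096 split
into windows starting at multiples of stride = 4096 − 512, so consecutive
full windows share exactly 512 tokens and the final window is truncated at
the note end; concatenating windows with overlaps removed reconstructs the
note exactly.

The scorer is pluggable (`fit(texts, labels)` / `score_batch(texts)`); this
is where a fine-tuned long-context transformer would sit in a production
system. The default is logistic regression over hashed, l2-normalized term
frequencies (2^15 features). l2 rather than l1 normalization matters: with
l1 the score distribution collapses to a band narrower than the between-fold
calibration drift, destroying pooled cross-fold ranking. Hashed rows are
cached and shared across folds — hashing is stateless and label-free, so the
sharing cannot leak labels.

Chunk scores reduce to a note score, and note scores to a patient class, by
one rule: keep the prediction with the largest |score − 0.5|. Ties (equal
margins on opposite sides, or a score exactly at threshold) resolve to the
positive class — deterministic and clinically conservative. The patient's
continuous score for ranking metrics is the winning prediction's score.
Scoring inputs default to notes dated ≤ index + 7 days, keeping
outcome-window documentation out of the predictors.

Medication extraction is rules-based: section headers (discharge/home
medications, medication history/changes/orders) open a 40-token section
body; lexicon matches anywhere are emitted with their enclosing section (or
"other"), normalized through an alias table (e.g. "LEV" → levetiracetam);
a negation cue ("no", "denies", "not", "discontinued", …) within the 3
preceding tokens flags the mention, and negated mentions are excluded when
harvesting note-only medications into structured records.

## Models, cross-validation and uncertainty

Two structured baselines: elastic-net logistic regression (saga, l1_ratio
0.5, class-balanced weights) and gradient-boosted trees (500 estimators, L1
and L2 regularization 0.1, other settings default, single-thread hist).
The families are specified behaviorally; bit-level agreement with any other
implementation is not a goal. The winning selection scheme differs by
family: prevalence filtering for the trees, χ² top-500 for the logistic
model.

Cross-validation is five-fold at the patient level (every note and feature
of a patient travels with it), each fold the held-out 20% once,
seed-shuffled, and — in the experiment driver — stratified by the evaluated
label. Stratification matters for calibration: without it a test fold rich
in positives necessarily trains on a positive-poor remainder, giving pooled
cross-validated scores a systematic pessimistic bias.

F1 and AUROC are computed from first principles (harmonic mean at the 0.5
threshold with F1 = 0 when there are no true positives; tie-aware
Mann-Whitney via midranks). The 95% CI for a cross-validated estimate is the
union of (a) the percentile bootstrap over patients of the pooled
predictions, 1000 resamples, single-class resamples redrawn and counted, and
(b) the Nadeau–Bengio corrected t-interval over fold metrics (variance
factor 1/k + 1/(k−1)), clipped to [0, 1]. Pooled CV predictions are
cross-correlated — scores in one fold depend on labels in others — so the
patient bootstrap alone under-covers; the fold interval alone is blind to
within-fold evaluation noise. Their union achieved nominal-or-better null
coverage in calibration runs; `bootstrap_ci` itself remains available as the
pure patient bootstrap.

## The synthetic generator

Each patient draws from an independently spawned child RNG stream, so
cohorts are byte-reproducible and per-patient noise is stable under
parameter changes. Latent recurrence status is Bernoulli
(`recurrence_prevalence`, drawn independently of the planted inclusion
violations), and drives post-index event rates: epilepsy-coded days
(Poisson 3.5 vs 0.15), status epilepticus (0.20 vs 0.01), ASM prescriptions
placed on epilepsy-coded days (0.55 vs 0.025), procedures with
confirmations, diagnostics, and inpatient fractions. Under these defaults
the composite fires for ~98% of latent-recurrent and ~11% of
latent-non-recurrent patients, so latent prevalences of 0.52 (EMR) and 0.59
(claims) realize composite prevalences near 0.57 and 0.63 — the latent rate
is calibrated to the observable composite, not the other way around. About
5% of patients violate each inclusion criterion; ~16% are infants at index,
exercising the special-case rule. Background diagnoses draw from a
Zipf-weighted pool of ~720 filler codes so the feature vocabulary has
realistic width and the selection schemes have work to do.

The structured signal dial plants label-conditional *pre-index* code rates
in two places: extra seizure-related codes on the index-day encounter and a
ten-code set of pre-index risk-marker diagnoses. Free-standing pre-index
seizure-like encounters would instead become the index event, so the
seizure-related part of the signal sits on the index day, inside the feature
window. Counts are inverse-CDF Poisson transforms of per-patient uniforms,
so raising the dial moves each affected patient's count monotonically; at
zero the two latent classes have identical pre-index distributions by
construction.

The text dial shifts the log-odds of a prognosis token set (and, opposite
in sign, a reassuring set) against a ~190-word clinical background
vocabulary, scaled per note type: neurology 0.50, communication 0.25,
discharge summary 0.20, EEG 0.10, MRI 0.05, CT 0.02 — a planted gradient
for the ablation harness, strongest where prognostic language plausibly
lives. Note lengths are log-normal with median 1019 tokens and ~5% of notes
over the 4096-token chunking limit; each patient gets a neurology note on
the index day plus ~Poisson(1) notes of other types within a week of index.
Notes also embed medication sections (sometimes abbreviated, sometimes
negated) whose appearance odds shift with the text dial, emulating
medications visible only in text.

What the generator does **not** emulate: disease progression or treatment
dynamics, laboratory values, demographic structure beyond sex and age at
index, coding drift over calendar time, inter-note correlation beyond the
shared latent status, and realistic clinical grammar (notes are bags of
tokens). Passing tests therefore demonstrate that the *logic* — windows,
positional rules, selection, aggregation, evaluation — is correct and that
the pipeline recovers planted signals and stays calibrated under a true
null; they say nothing about predictive performance on real clinical text.

## Problem sizes

Tests and the acceptance script run cohorts of 200–2000 patients: 2000 is
where the binomial noise on a prevalence or AUROC is a few percent —
adequate for calibration and ordering checks — while labeling-oracle
equivalence uses many small seeded cohorts (50 × 200) to cover more of the
event-pattern space. Bootstrap CIs use 1000 resamples except in secondary
ablation tables (200).

## Known limitations

- The supplementary-grade code lists (full broad index set, utilisation
  thresholds, complete ASM list) are registry defaults, user-replaceable.
- The transformer scorer is an interface, not an implementation; the default
  term-frequency model is a deliberately simple stand-in that honors the
  same contract.
- Same-day medication–encounter linkage can over-join on busy days.
- The all-cause-utilisation criterion's threshold dominates its behavior;
  cohorts with denser baseline utilisation than the generator's would need
  it re-tuned.
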