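# Methods

## Problem and scope

`strokecall` implements and tests a machine-learning pipeline for recognising
stroke in prehospital medical-helpline calls. The real task: call-takers on a
non-emergency medical helpline triage callers, selecting a diagnostic
category and deciding on ambulance dispatch; hospital-confirmed stroke/TIA
admissions are recorded in a national stroke registry keyed by the civil
registration number, which permits linking each call to ground truth. Human
triage recognises roughly half of stroke calls (sensitivity ≈ 52.7% at PPV ≈
17.1%); a text classifier operating on call transcripts can do substantially
better. The original call data are legally restricted, so this package pairs
every analysis component with a synthetic-cohort generator that reproduces
the statistical structure the analysis depends on. Speech recognition is out
of scope: transcripts enter the pipeline as token sequences.

## Synthetic cohorts (what is emulated, what is not)

The generator plants, per call: line (10% emergency line, used only as
supplementary training data), calendar placement (the test year carries 27%
of call volume, mirroring the reference cohort's 2021 share), ground-truth
stroke status (helpline prevalence 0.25%, emergency line 2.5%), demographics
conditional on status (age truncated-normal 71 ± 13.4 vs 44 ± 20 years on
[18, 105]; female fraction 0.461 vs 0.555), registry entries with onset
offsets (uniform on [−48 h, +12 h], plus a 5% fraction planted outside the
[−72 h, +24 h] linkage window and 5% typed subarachnoid haemorrhage, both of
which ground-truth labelling must reject), a 40% missing-diagnostic-category
rate, and call-taker triage labels drawn at the configured sensitivity with
the false-positive rate implied by (prevalence, sensitivity, PPV):

    FPR = p·sens·(1 − PPV) / ((1 − p)·PPV)  ≈ 0.0064 at the defaults.

`stroke_prevalence` is defined as the rate of *ground-truth-positive* calls;
SAH and out-of-window registry entries are generated on top of that rate, so
the prevalence the evaluation sees equals the configured value in
expectation and the call-taker simulator realises the configured
sensitivity/PPV by construction.

Transcripts are bags of Zipf-distributed background tokens (synthetic
lexicon of 2,000 words, exponent 1.1, mean length 40) into which ten stroke
indicator words (dispatch terms, laterality, deficit descriptions) are
injected at rate 0.4 per word in stroke calls (0.005 leakage elsewhere), and
ten distractor words symmetrically for non-stroke calls. A token-substitution
knob emulates transcription noise; it defaults to 0 because no error
structure for the upstream recogniser is available. Not emulated: Danish
language, discourse structure, transcript-length/selection effects, audio.
Passing tests therefore demonstrate the *machinery* (linkage, training,
calibration, inference, explainability) under a known signal, not
performance on real calls.

## Linkage and splitting

A call is ground-truth positive iff a non-SAH registry entry for the same
patient has onset within the closed window [call_start − 72 h, call_start +
24 h]; among several qualifying entries the nearest onset is kept (only the
boolean matters downstream). A call whose only match is SAH is negative; a
call with both an SAH and a qualifying non-SAH entry is positive. A missing
patient id labels negative with a warning rather than an exception.
Call-taker positive = stroke category selected AND ambulance dispatched.

Helpline calls of the test year form the test set; those without a
diagnostic category are held out separately (call-taker performance cannot
be scored on them). Earlier helpline calls are split 10%/90% into validation
and five training folds by stratified sampling on (ground truth, category
present), with round-robin assignment after a seeded shuffle so per-fold
positive counts differ by at most one per stratum. Category-missing calls
go to training folds only. Emergency-line calls are training-only; those in
the test year are discarded to avoid temporal overlap.

## Features

Bag-of-words counts over word n-grams (default range 1–2) and character
n-grams computed within word boundaries with a `#` marker on each side
(default 3–5; `abc` → `#ab`, `abc`, `bc#`). Tokens are lower-cased with
edge punctuation stripped, which makes "word" well-defined for occlusion.
The vocabulary is built on training folds only: document-frequency filter
(min_doc_freq = 5) then, if needed, a cap at 50,000 features keeping the
highest document frequencies with lexicographic tie-break — a standard,
deterministic selection chosen because the original selection procedure is
not public. Counts (not binary presence) are the cell values. The reference
study uses word unigrams only: the planted signal is unigram-level and this
keeps the occlusion candidate set identical to the feature set.

## Classifier

An ensemble of five identical multi-layer perceptrons (single scalar output
through a sigmoid), trained with binary cross-entropy and Adam on sparse
count vectors. Member *k* uses training fold *k* for early stopping on
F1 at threshold 0.5 (patience 5 epoch-end evaluations, best checkpoint
restored) and trains on the other four folds plus the emergency-line data;
an ablation flag drops the latter. The network is implemented directly in
numpy so the exact pre-sigmoid logit is available (threshold centring and
occlusion operate in logit space) and so initialisation, batching and
dropout are all governed by one seed; training is bit-deterministic given
the seed. Defaults (one hidden layer of 32 ReLU units, lr 1e-3, batch 256,
≤ 20 epochs, L2 1e-5, no dropout, no class reweighting) are sized to the
synthetic scale and fully overridable; a configurable grid search selects by
validation F1 of the calibrated ensemble (ties to earliest grid order), with
an 8-point demonstration grid shipped.

## Threshold calibration and ensembling

On the validation split, each member's decision threshold τ_n is the
harmonic mean 2ab/(a+b) of two operating points searched over the finite
grid of observed scores plus {0, 1} under the ≥ convention: t_sens, the
largest threshold whose sensitivity still reaches the call-takers'
sensitivity, and t_ppv, the smallest threshold whose PPV reaches the
call-takers' PPV (an unattainable reference PPV raises an error naming the
maximum attainable value). Members are combined by centring each logit at
logit(τ_n) and taking the sigmoid of the mean centred logit, giving the
ensemble the common decision threshold 0.5. The original supplementary
equations for this step are unpublished; the formulas here are reconstructed
literally from the main-text description. Calibration uses the validation
split, never test (which split the original used is unstated; validation is
the conservative choice).

## Evaluation

Reported metrics: F1, sensitivity, PPV, FOR = FN/(FN+TN) and FPR =
FP/(FP+TN) — on this imbalance NPV and specificity are ≈ 1 and their
complements carry the information. Results aggregate 11 seeded training
runs: metric means, percentile-bootstrap 95% CIs (calls resampled with
replacement, metric averaged over runs per replicate, undefined replicates
skipped and counted; default 1,000 replicates), and one-sided approximate
permutation tests with add-one smoothing p = (1+#{null ≥ obs})/(1+n_perm)
(default 10,000 draws). Paired tests (same calls) swap each call's
prediction pair with probability ½, one mask shared across runs, statistic =
run-averaged metric difference; the call-takers' single deterministic vector
is broadcast across runs. Independent tests (disjoint subsets) reassign
calls between groups preserving sizes. The alternative direction is a
required argument — it is not inferred from the data. No multiple-testing
correction is applied (none is in the design being reproduced). ROC and
PPV-sensitivity curves are computed at every distinct score threshold; the
ROC is the step function from (0,0) to (1,1) and the PR curve's full-recall
endpoint has PPV equal to prevalence. Confusion matrices are reported as
rounded means over runs.

## Occlusion explainability

Word impact on a document is the mean over members of the raw-logit drop
when all instances of the word are removed before vectorisation (every word
and character n-gram touching the word disappears). Logits, not sigmoid
scores, are differenced: near 0 or 1 the score difference is squashed toward
zero. Words are ranked by the signed-square sum of impacts over the analysed
group, which favours rare high-impact words; candidates are the vocabulary's
word unigrams, and a word absent from a document contributes an exact zero.
The analysed groups are the median-validation-F1 run's predicted-stroke and
predicted-non-stroke test calls; the strict median requires an odd run
count (the pipeline's explicit rule for an even count is the lower middle
order statistic). In the full pipeline the predicted-non-stroke group is
ranked on a seeded subsample (default ≤ 2,000 documents) since that group
contains nearly the whole test set.

## Model/Results interface

The package exposes a statsmodels-style surface: `StrokeCallData.prepare`
builds the analysis-ready dataset from a cohort, `StrokeRecognitionModel`
holds data plus hyperparameters, and `fit(n_runs, seed)` returns a
`StrokeRecognitionResults` carrying per-run ensembles and thresholds,
aggregated metrics with CIs, permutation comparisons, curves/plots, the
occlusion analysis and a text `summary()`. The stage modules (`synthetic`,
`linkage`, `features`, `classifier`, `calibration`, `evaluation`,
`occlusion`) remain independently usable; `pipeline.run_pipeline` and the
`strokecall` CLI orchestrate them with per-stage seeds derived from one
global seed.

## Numerical choices and degenerate inputs

Sigmoid via tanh for stability; logit as log(p) − log1p(−p). Permutation
counts use a 1e-12 slack on the ≥/≤ comparison so ties count as extreme.
Metric ratios are exact double divisions; undefined ratios (empty
denominator) are NaN and flagged, never silently zero. Single-class training
data, empty corpora, empty comparison groups, thresholds outside (0, 1) and
infeasible (prevalence, sensitivity, PPV) triples all raise with a message
naming the offending quantity. Fold assignment errors name the stratum that
is too small — which is why the 2,000-call smoke configuration raises the
planted prevalence to 5%: at 0.25% such a cohort has fewer positive calls
than folds.

## Problem sizes

The reference study runs 50,000 calls, prevalence 0.25%, 11 runs × 5
members (≈ 2.5 minutes on one CPU); the smoke configuration runs 2,000
calls and 2 runs end to end (≈ 7 s). Monte-Carlo checks use 400 null
replicates at 2,000 permutations for test size and 200 replicates for
bootstrap coverage. These sizes are the package's own choices for a
synthetic-scale study; all are configurable.

## Known limitations

Synthetic transcripts are bags of tokens with independent injection — no
syntax, no topical correlation, no transcription-error structure; absolute
metric values on them say nothing about real calls (the reference study's
sensitivity/PPV far exceed the published real-data values precisely because
the planted signal is strong). The emergency-line and helpline transcripts
share one background distribution, so the domain-mismatch phenomenon the
ablation probes is only structural. With 0.25% prevalence at 50,000 calls
the test split holds only ~20 stroke calls, so run-to-run variability in
sensitivity is large; the paired permutation test accounts for this but
comparisons remain coarse at this scale. Grid search retrains one ensemble
per grid point and is the one stage whose cost grows multiplicatively.
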