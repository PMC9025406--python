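# Methods

This note documents the models and conventions behind `visitrisk`: what the
synthetic cohort generator simulates, how the case/control pipeline is
defined, how the sequence classifiers are implemented and trained, and the
statistical conventions of the perturbation-based contribution analysis.
It also records the design decisions that were genuinely open and why they
were resolved the way they were.

## 1. Synthetic cohort generator

### Generative model

Each of `n_patients` patients is simulated independently (per-patient RNG
substreams, so output is reproducible and independent of patient order):

* **Encounters** arrive as a homogeneous Poisson process with rate
  `encounter_rate` per patient-year over `study_span_days`, rounded to
  integer days; same-day arrivals merge into one encounter. Every encounter
  records at least one diagnosis (the visit reason).
* **Events per encounter**: per domain (diagnosis, medication, lab), a
  Poisson-distributed number of codes is drawn from a Zipf distribution
  with exponent `code_frequency_skew` over the domain vocabulary
  (duplicates within an encounter collapse). Lab events carry a
  `RESULT_FLAG` drawn from `lab_flag_probs` over
  NORMAL/ABNORMAL/HIGH/LOW.
* **Outcome (SRE) hazard**: at each encounter the probability of a
  suicide-related event within the following `horizon_days` (90) is

      logit(h) = logit(base_hazard) + Σ_e log_odds_e · n_e ,

  where `n_e` counts occurrences of planted code *e* in the 365 days up to
  and including the encounter. For planted *lab* codes only
  abnormal-flagged occurrences count: an in-range result carries no risk
  information, mirroring the abnormal-only filter applied at modelling
  time. (Without this convention roughly half the lab exposure would be
  invisible to any model trained on abnormal labs, and the planted lab
  effects would be unrecoverable by construction.)

### The identifiability convention

When the hazard draw succeeds, the SRE is recorded **exactly 90 days after
the triggering encounter**, and no encounters are generated strictly
between trigger and SRE (an acute episode interrupting routine care). This
convention was chosen deliberately: it makes the configured hazard exactly
identifiable from the released tables. The scan statistic "fraction of
encounters followed by an SRE within 90 days" then equals the per-encounter
hazard in expectation, because each SRE is inside the 90-day window of its
trigger and of no other encounter. With any random placement of the SRE
inside the window, the overlapping windows of neighbouring encounters make
the scan fraction roughly double the per-encounter hazard at realistic
visit densities, and no simple calibration check is possible.

A consequence is that in synthetic data each SRE yields exactly one
case-eligible encounter, so the augmentation mechanism (several case
samples per event) is exercised by hand-constructed timelines in the unit
tests rather than by the generator.

### What the generator does and does not emulate

Emulated: irregular multi-year visit timing, power-law code frequencies,
three event domains with namespaced vocabularies, lab flags, sparse
event-anchored outcomes with known risk/protective drivers, PTSD diagnosis
dates. Not emulated: demographics, numeric lab values (flags only),
prescription-fill adherence, death/censoring, coding-system drift over
calendar time, inter-patient correlation, care-seeking feedback (sicker
patients visiting more). Passing the recovery tests therefore demonstrates
that the pipeline is correct and well-calibrated under an additive-logit
world; it does not certify performance on real EMR data, where none of the
simplifications above hold.

## 2. Cohort construction

Interval conventions (all arithmetic in days; "3 months" is fixed at 90
days, "1 year" at 365):

* outcome window: half-open `(index, index + 90]` — an SRE on the index
  date cannot define the label;
* lookback: half-open `(index − 365, index]` — the index encounter's own
  events belong to the history;
* washout: closed `[index − 365, index]` — any SRE there excludes the
  encounter.

Cases are augmented (every eligible encounter within 90 days before an SRE,
duplicate index dates collapsed); controls are collapsed to the latest
eligible encounter per patient. A patient contributing case samples
contributes no control sample — the conservative reading where patient-level
reuse across arms is not allowed. Controls are undersampled uniformly
without replacement (seeded) to the case count; a control deficit keeps all
controls and logs a warning. The 8:1:1 split is by patient by default:
augmentation creates near-duplicate samples of one patient, and a
sample-level split would leak them across partitions (sample-level remains
available as `split_unit="sample"` for fidelity experiments).

## 3. Feature encoding

* Lab events are filtered to `RESULT_FLAG ∈ {ABNORMAL, HIGH, LOW}`
  (case-insensitive, trimmed) and to the `k_labs` (default 709) most
  frequent lab codes; frequency is counted after the abnormal filter.
* ICD-9 diagnosis codes are mapped through a CMS GEM table (combination
  rows contribute every target; no-map rows none), then all diagnosis codes
  are truncated to the 3-character ICD-10 category.
* Medication names are normalized (lowercase; dose/unit/form tokens and
  numerals stripped; idempotent) and looked up exactly; misses are dropped
  with a count.
* Tokens are namespaced (`DX:`, `MED:`, `LAB:`) to prevent cross-domain
  collisions. One token per lab code regardless of flag direction — the
  abnormal flags gate inclusion but do not split tokens; the post-hoc flag
  composition question is served by `flag_proportions` instead.
* The vocabulary (indices from 1; 0 reserved for padding) is built from the
  **training partition only**, capped at `max_vocab` (default 30,000) by
  corpus frequency with lexicographic tie-breaks; out-of-vocabulary tokens
  are dropped at encode time with a running count. Feature-domain ablations
  are applied at encode time (tokens filtered before the vocabulary is
  built), so ablated runs share the cohort and split and differ only in the
  feature space.

## 4. Sequence models

The classifiers are implemented directly in NumPy (embedding + stacked
LSTM/vanilla RNN + sigmoid read-out, full backpropagation through time,
Adam); the implementation is validated against numerical gradients for both
architectures in the test suite and is bit-deterministic under a fixed seed
with single-threaded BLAS.

* Within a visit, token embeddings are summed (`visit_aggregation="mean"`
  available). Visit order enters through the recurrence; elapsed-time gaps
  are retained in the data model but not consumed by these architectures.
* Batches are right-aligned and masked; masked steps carry state through
  unchanged, so a sample's score is independent of batch composition and
  padding. An empty (all-OOV) history yields the deterministic
  padding-only score.
* Reference hyperparameters are the package defaults: embedding 128,
  hidden 128, dropout 0.2 between recurrent layers, 2 layers, input size
  30,000, early-stopping patience 3 (epochs without validation-AUROC
  improvement; best-validation weights restored). Optimiser settings the
  reference configuration leaves open are fixed as defaults here: Adam,
  learning rate 3e-3, batch size 64, max 30 epochs, binary cross-entropy
  on the final-state score.
* **Linear logit bypass** (`linear_bypass`): an optional linear read-out
  from the pooled (sequence-summed) visit embeddings added to the recurrent
  logit. Risk that is additive on the logit scale — the standard
  epidemiological assumption, and exactly the synthetic ground truth — is
  then representable without pushing the saturating cell state; this both
  raises held-out AUROC toward the Bayes ceiling and, more importantly,
  stabilises perturbation attributions (§5). Off by default; on in the
  study preset.
* AUROC is the Mann–Whitney pair statistic, computed from ranks with tie
  handling and pinned to an exhaustive O(n²) pair oracle at 1e-12 in tests.
* `repeat_runs` repeats training with seeds differing only in
  initialisation/shuffling/dropout and reports mean and sample standard
  deviation (ddof = 1) of validation and test AUROC.

## 5. Contribution analysis

**Feature contribution (FC).** For a patient and feature, each occurrence
of the feature is removed from the input sequence one at a time (others
intact; a visit emptied by the removal is dropped, matching the encoder's
treatment of empty visits) and the score deltas are summed. Masking to
padding instead of removal is not offered because with summed visit
embeddings the two are identical.

**Scale.** Deltas are measured on the logit scale by default
(`fc_scale="probability"` available). This choice is forced by the
geometry of the sigmoid: on the probability scale the removal delta of a
genuine risk feature is proportional to `p(1−p)` at the patient's risk
level, so event patients — who sit on the flat upper part of the curve —
show *smaller* deltas than event-free carriers, and the RC of a true risk
feature lands below 1. On the logit scale the per-occurrence delta of a
near-additive model is approximately the feature's effect size for every
patient; the effect cancels in the event/no-event ratio and RC measures
the occurrence-burden contrast between the groups, which is the quantity a
risk-factor screen is after.

**Grouping.** By default every patient contributes one FC row per feature —
zero when the feature is absent (a feature that never occurs contributes
nothing) — and m/n count all patients with/without the event, the literal
reading of the variance formula. The empirical reason is decisive: with ±2
log-odds planted effects, the per-carrier occurrence-count contrast is only
~1.05–1.15 while the carrier-prevalence contrast is ~3-fold; conditioning
on carriers throws away the prevalence signal and planted risk features no
longer separate from 1. Carrier-only grouping remains available
(`group_mode="carriers"`) for sensitivity analyses. Support is always
judged on carriers: a feature needs `min_support` (default 10) carriers in
*both* groups, or it is excluded.

**Sign rule.** RC is the ratio of group means and requires the means to
share a sign; protective features necessarily have negative removal-FC in
both groups and yield RC < 1 when events carry the smaller (in magnitude)
burden. Opposite-sign or zero means exclude the feature as `sign-invalid`.
Requiring *positive* means would exclude every protective feature, which
contradicts the screen's purpose. Exclusions are reported in their own
table with reasons, never silently dropped.

**Inference.** `Var(ln RC)` uses sample standard deviations (m−1, n−1);
the 95% interval is log-symmetric (`low·high = RC²`, used in tests and as a
published-value consistency check); the p-value is two-sided normal on
`ln RC/√Var`; Bonferroni uses N = number of features actually tested
(post-exclusion, recorded in the report); Benjamini–Hochberg q-values are
reported alongside. The significance filter is
`p_Bonferroni < 0.05 AND (CI_low > 1 OR CI_high < 1)`, with direction
labelled risk (RC > 1) or protective (RC < 1).

**Per-patient unit.** For case patients with several augmented samples, FC
is computed on the sample anchored closest to the event
(`sample_mode="mean"` averages over samples instead).

## 6. Study conditions and problem sizes

The planted-effect evaluation (`visitrisk.presets`) fixes: 6,000 patients,
5-year span, 8 encounters/year, base 90-day hazard 0.0015 per encounter,
and ten planted effects of ±2 log-odds (three risk and one protective
diagnosis category, two risk and one protective medication, two risk and
one protective lab), placed at mid-frequency vocabulary ranks so that
carriers are common enough for support but most patient-years carry no
exposure. The study model narrows the architecture to embedding 48, hidden
48, one layer, with the linear bypass and weight decay 1e-3 — small enough
that a full training run takes seconds on one CPU while leaving the
architecture family unchanged. Under these conditions the held-out test
AUROC is 0.90–0.92 across seeds, the feature-ablation ordering
(dx+med+lab ≥ dx+med ≥ dx) holds on every tested seed, all ten planted
effects pass the significance filter in the correct direction, and 1–5% of
null features pass the Bonferroni filter.

## 7. Numerical choices

* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; per-patient generation uses spawned
  substreams keyed to the population seed.
* Ranking ties (lab top-k, vocabulary) break lexicographically;
  undersampling and splits are seeded permutations; the patient split
  allocates `round(n·8/10)` / `round(n·9/10)` boundaries.
* Probabilities are clipped to `[1e-9, 1 − 1e-9]` before the logit
  transform in the contribution analysis; a zero-variance feature gets
  p = 1 at RC = 1 and p = 0 (with a degeneracy warning) otherwise.
* Significant figures: RC and CI bounds render at 3 s.f. in the published
  table format; all stored values keep full precision (rounding is
  display-only).

## 8. Known limitations

* The contribution analysis inherits the model's biases: context effects
  in the recurrent path create a small systematic case/control asymmetry in
  removal deltas for high-frequency null features, which is why the null
  false-pass bound is stated at the study scale rather than as a universal
  guarantee. The linear bypass and weight decay reduce, but do not
  eliminate, this asymmetry.
* RC is an association measure over model attributions, not a causal
  effect; the printed direction labels describe the model's learned
  dependence under the study's sampling design.
* The dilated/quasi-recurrent/time-aware/attention architecture variants
  of the reference framework are out of scope; the module boundary admits
  adapters (any scorer exposing `predict` over encoded samples works with
  the contribution analysis).
* Real-EMR ingestion is limited to the documented long-format tables; no
  OMOP/FHIR connectors.
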