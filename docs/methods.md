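# Methods

## Overview

The package reimplements a urine-proteome monitoring workflow for bladder
cancer follow-up as a reusable pipeline with two arms: a cross-sectional
differential-abundance analysis (recurrence vs no-recurrence) and a
longitudinal per-patient pathway index (PPi/dPPi) with an intervention alert.
All computation lives in `src/dppi`; the `analysis/` drivers are thin
narratives over it.

## Data model and preprocessing

Intensities are MaxLFQ-style label-free quantification values. A raw value
of exactly 0 is treated as *not detected* and stored as missing, which is
the premise of the left-censored imputation model and of counting absent
signature proteins as 0 in the index sums.

Preprocessing order (differential arm): technical replicates are averaged on
the **raw** intensity scale (mean of the observed replicates; missing only
if all replicates are missing), then log2-transformed, then filtered to
proteins with ≥ 50% valid values in at least one clinical group (boundary
inclusive: 2/4 valid passes at 0.5 — with a group of 13, 7 valid are
required), then imputed.

Raw-scale replicate averaging was chosen because the index (below) sums raw
LFQ values; mean-of-observed rather than missing-propagation maximises
longitudinal coverage and is switchable by pre-masking.

**Imputation.** Missing log2 values in a column with observed mean m and
standard deviation s are drawn independently from
Normal(m − 1.8·s, (0.5·s)²) — width 0.5, downshift 1.8, the common Perseus
parameterisation for detection-limit dropout. Imputation is per column
(per sample); whole-matrix mode is available via `per_column=False`. Draws
are seeded and only ever written into cells that were missing. Under these
defaults the probability an imputed value exceeds its column mean is
Φ(−3.6) ≈ 1.8·10⁻⁴. Imputed values are used **only** for testing and
clustering, never in the index sums: injecting simulated raw-scale values
into PPi would fabricate signal.

## Differential testing

The per-protein statistic is the SAM-style moderated t:
d = (x̄₁ − x̄₂) / (SE_pooled + S0), with the pooled-variance (Student)
two-sample standard error and S0 = 0.1 by default. The classic t (S0 = 0) and
its two-tailed p-value (t distribution, n₁+n₂−2 df) are reported alongside.
Groups are ordered case-first: log2 fold change is recurrence minus
no-recurrence.

FDR is estimated by label permutation with the ratio-of-counts estimator:
for cutoff c on |d|, FDR̂(c) = (mean permutation count of |d*| ≥ c) /
max(1, observed count of |d| ≥ c), with the proportion of true nulls fixed
at 1 (conservative). The significance cutoff c* is the smallest observed |d|
with FDR̂ ≤ the target (0.05 default). Default 250 seeded random relabelings;
when the number of distinct label assignments is ≤ 10,000, all of them are
enumerated instead, making the result exact and seed-independent (this
always happens for the small per-patient designs). The published tool's
exact significance-curve construction is not public; the single-cutoff
estimator above is the standard formulation and is what the tests and
oracle comparisons verify.

Column clustering is scipy average-linkage on Euclidean distances, with
optional row z-scoring, exported as Newick. A k-means row-collapse
preprocessing is exposed but off by default — at these data sizes it only
changes runtime.

## The PPi/dPPi index

The signature is bundled as a versioned GMT file: seven pathways (P1–P7,
GO and Reactome accessions) whose member lists dedupe to **34** distinct
gene symbols. (The source text accompanying the table speaks of 35 related
proteins while the printed member lists contain 34 distinct symbols; the
package bundles exactly the printed lists and does not invent a 35th.)

PPi(patient, t) is the sum of raw LFQ intensities over the matched
signature proteins, computed on raw or replicate-averaged matrices only.
Gene matching is case-insensitive and splits semicolon-joined protein-group
entries; a group matches if any of its symbols matches. Per-pathway sums
count shared proteins in every pathway listing them; the total counts each
union member once, so total ≤ Σ per-pathway.

dPPi(t_y) = (PPi(t_y) − PPi(t₁)) / PPi(t₁), always against the onset
baseline. Percent values are rounded half-away-from-zero to integers. A
zero overall baseline is an error; a zero per-pathway baseline makes that
pathway's dPPi undefined (reported as missing) without affecting the total.
Exact identities (tested): baseline dPPi ≡ 0; global rescaling of all
intensities leaves dPPi unchanged; multiplying every signature protein by m
gives dPPi = m − 1; with non-negative intensities dPPi ≥ −1.

**Alert rule.** Alert iff dPPi percent ≥ threshold, default −5. The recorded
recommendations in the bundled 16-row follow-up table are separated by any
threshold in (−7, −3): interventions were recommended at −3 and −2 but not
at −7. −5 is the midpoint of that interval and is a prominent config knob,
not a tuned constant. At this default the replayed table is 100% concordant.
The bundled table keeps the printed per-visit values; one narrative value in
the source (+35% for the first patient's second visit) disagrees with the
printed 20 — the table value is used and the discrepancy documented here
rather than reconciled.

## Synthetic data

The generator is first-class, tested code and defines the study conditions:
13 recurrence vs 17 no-recurrence patients, two technical replicates per
patient, 400 proteins. Protein baseline log2 means are uniform on [20, 32]
(the realistic LFQ dynamic range), biological SD 0.5, replicate SD 0.2 in
log2 units. Group effects add a log2 shift (default 1.0; 2.0 in the recovery
benchmarks) to the signature proteins in the recurrence arm. Missingness is
MNAR-logistic: P(missing | log2 v) = 1/(1 + exp(slope·(v − midpoint))) with
midpoint 22, slope 1, giving ~15–20% missingness concentrated at low
abundance — the minimal model under which downshift imputation is sensible.

Longitudinal courses multiply the signature proteins' raw intensities by an
event-driven disease multiplier (e.g. recurrence 2.0, post-resection 0.3),
so the true dPPi is analytically multiplier − 1.

What the generator does **not** emulate: peptide-level effects, MaxLFQ's
internal normalisation, correlated protein co-regulation, batch effects, or
inter-visit biological drift in non-signature proteins. Passing tests
therefore demonstrate correctness of the computation and calibration of the
statistics under the stated model, not clinical validity on real cohorts.

## Numerical behaviour and limitations

- Because PPi sums raw intensities, it is dominated by the few most
  abundant panel proteins; with replicate SD 0.2 a single visit's recovered
  dPPi can deviate by tens of percentage points at large multipliers (the
  mean absolute error over many simulated courses is < 0.05). The alert
  threshold's margin absorbs this in the monitored regime, but single-visit
  dPPi values should be read with that noise in mind.
- Zero variance with equal group means yields d = 0, p = 1 rather than an
  error; zero variance with unequal means yields an infinite classic t
  (p = 0) and a finite moderated d when S0 > 0.
- Permutation results are bit-reproducible given a seed; exhaustive mode is
  deterministic without one. All pipeline stages derive their seeds from the
  single run seed by hashing the stage name.
- Benchmark problem sizes (20 seeds for effect recovery, 50 null repeats,
  200 simulated courses, 10⁴ imputation draws) were chosen as the point
  where the Monte-Carlo error is comfortably below the margins being
  checked.
- The concordance replay uses the recorded per-visit index values; it
  validates the alert rule, not the upstream mass-spectrometry pipeline.
  Recomputing the per-patient indices from the deposited raw tables is
  wired up (`analysis/05_replicate_published.py`) but requires the user to
  supply those tables locally.
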