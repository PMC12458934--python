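# Methods

## Problem setting

Tumor DNA sheds into blood plasma as a small, dilute fraction of total
cell-free DNA (cfDNA). CpG loci whose methylation in healthy blood sits at
an extreme of the beta scale (essentially 0 or essentially 1) with minimal
variance make sensitive detectors: any appreciable deviation from the
extreme at such a locus is evidence of non-blood, possibly tumor-derived,
DNA. `methylpanel` implements the full marker-panel workflow around this
idea: selecting two kinds of panels from array-style beta matrices, calling
tumor vs normal by an OR rule over binarized markers, assigning tissue of
origin by distance to per-class binary profiles, thresholding plasma
sequencing signal against control maxima, extracting read-level cumulative
methylation-density features from targeted sequencing, and evaluating
everything under leave-one-out cross-validation.

## Marker selection

Input is a probes × samples beta matrix in [0, 1] with group labels
`reference`, `<type>.N` (normal tissue) and `<type>.T` (tumor). Per probe
the reference median and SD and per-group medians are computed over
non-missing values; a probe with more than `max_missing_frac` (default 20%)
missing in any group is dropped — medians are robust, but coverage has to
be bounded.

A **detection (T-N) candidate** must satisfy, with defaults in parentheses:

1. reference median ≤ `ref_low_max` (0.1) or ≥ `ref_high_min` (0.9);
2. reference SD ≤ `ref_sd_max` (0.07 — the variability bound that holds for
   the bulk of blood-reference probes on large peripheral-blood datasets);
3. at least one tumor type with |type median − reference median| ≥
   `delta_tumor` (0.3);
4. every normal-tissue group median within `eps_normal` (0.1) of the
   reference median.

A **classification candidate** replaces (4): the *negative* tumor types
must themselves look like the reference. Two readings of "look like" are
exposed via `neg_mode`: within `eps_normal` of the reference median
(default) or inside the reference-extreme band itself (`extreme_band`,
strictly harder). Normal-tissue concordance is deliberately not required
here — the classification panel targets tumor-type contrasts, not
tumor-vs-normal contrasts.

The **detection panel** is assembled by greedy set cover: repeatedly add the
candidate covering the most still-under-covered (type, slot) pairs until
every declared type is detected by `min_probes_per_type` (2) probes. Ties
break by larger minimum median shift over covered types, then probe id, so
assembly is deterministic. Infeasibility (a type with too few covering
candidates, or a `max_panel_size` cap reached short of coverage) raises an
error naming the type. Greedy multicover is not guaranteed minimum-size in
general; the tests verify coverage against an exhaustive-subset oracle on
small pools.

The **classification panel** comes from greedy information-gain forward
selection: each candidate's binarized per-class median profile partitions
the classes (classes sharing the accumulated bit profile form one block);
the candidate minimizing the class-count-weighted conditional entropy of
that partition is added, until the entropy reaches 0 (all classes plus the
reference split), a target size is reached, or no candidate strictly
reduces entropy (best-effort panel, warning listing merged classes).
Candidate order is shuffled once from the seed, so tie-breaking — and hence
the result — is deterministic under (pool, seed). Greedy selection can miss
XOR-like probe pairs whose individual gain is zero; this is the accepted
trade-off of a forward search.

## Binarization and cutoffs

Per-probe cutoffs sit midway between the reference extreme and the minimal
qualifying tumor deviation: `ref_median + delta_tumor/2` for low-reference
probes, mirrored for high-reference. A sample's beta binarizes to 1 iff it
is strictly beyond the cutoff in the direction away from the reference
extreme; the strict comparison maps boundary values to 0, so
reference-looking samples never trip a marker by a tie. Missing betas are
masked: they count as 0 for the tumor/normal call (absence of evidence) and
are excluded pairwise from distances.

## Tumor/normal call and tissue-of-origin classification

Detection is the OR rule — tumor iff any unmasked bit is 1. An all-masked
profile is reported `indeterminate`, never silently normal.

Classification builds one signature per tumor type plus the blood
reference: the class profile is the binarization of per-class per-probe
median betas, and all member profiles are stored. Distances from a sample's
bit vector use either the mean Euclidean distance to every class member
(`per_sample_mean`, default) or the distance to the class profile
(`centroid`); both are kept because "mean distance to each type" is
ambiguous between them. Masked positions are excluded pairwise and the
distance rescaled by `sqrt(panel_size / n_used)` so values stay comparable
across missingness patterns (an unmasked Hamming distance k gives exactly
`sqrt(k)`).

Decision criteria:

* **best match** — arg-min distance; ties resolved by "reference loses to
  any tumor class", then lexicographic label (minimum-rank ties keep the
  rank-based criteria permissive, matching their inclusive intent);
* **rank ≤ 2** — the true class counts as recovered if its minimum rank is
  ≤ 2;
* **within range** — all classes within δ of the best match (default
  anchor; guarantees a nonempty set containing the best match) or within δ
  of the sample itself (the literal reading, retained as an option; empty
  sets then count as misses).

Two distance adjustments correct for class-specific self-distance scales.
**QFfit** scores a distance by its empirical quantile within the class's
training self-distance distribution (ties at half weight); self-distances
leave the member itself out when the class has > 1 member, matching how an
unseen sample is scored (singleton classes contribute 0). The
**naive-Bayes** adjustment estimates per-probe Bernoulli rates with a
Laplace pseudocount of 1 and multiplies likelihoods over unmasked bits;
"Bayes" uses a uniform class prior and "Bayesf" the class-frequency prior.
Both forms are reconstructions of behaviourally specified adjustments; the
exact original formulations were not available, so the implementations here
are the package's own documented definitions.

## Plasma signal-fraction thresholding

Around each panel CpG a ±200 bp window is built (half-open
`[site−200, site+201)`; the "within 200 bp" phrasing does not fix
inclusivity, so this convention is fixed and configurable). All methylated
and unmethylated CpG calls over reads in the window are pooled into (cm,
cu); the signal fraction is `x = cm/(cu+cm)` at low-reference loci and
`cu/(cu+cm)` at high-reference loci, so tumor signal always pushes x up.
Zero coverage makes x undefined — it propagates as missing and never
counts as evidence. Per-region thresholds are the maximum defined control
x; a case region scores 1 iff x strictly exceeds the threshold, and the
sample call is the OR over regions. Resubstituting the controls against
their own thresholds yields exactly zero positives by construction (nothing
strictly exceeds its own cohort maximum) — this is a training-set property,
not an unbiased specificity estimate. For an *exchangeable* null cohort,
order statistics put a floor on cross-arm exceedance: a new sample strictly
exceeds the max of n controls with probability ≈ 1/(n+1) per region (less
under discreteness ties), so the per-sample OR over R regions approaches
`1 − (n/(n+1))^R`. The test-suite's label-swap check therefore asserts the
absence of any excess over this bound and of direction asymmetry, rather
than a literal zero rate.

## Read QC, filtering, and cumulative features

Sample-level conversion QC pools non-CpG (CHH/CHG) methylation over all
reads; a rate strictly above 3% fails the sample (incomplete conversion
inflates apparent methylation globally). Read filters apply in a fixed
order with per-stage counts: mean base quality < 20; more than 8 methylated
non-CpG cytosines (an unconverted molecule); non-missing CpG calls covering
< 90% of the region's CpGs. The filters are independent predicates, so the
surviving set does not depend on the order; the order only shapes the
per-stage attrition log.

Per-read percent methylation divides the methylated count by the region's
*full* CpG count, treating uncovered CpGs as unmethylated — a deliberate
downward bias that keeps the denominator consistent across reads.

The per-region feature block is cumulative: under the default `or_higher`
convention, feature k (k = 1..n_cpg) is the fraction of retained reads with
≥ k methylated CpGs ("> (k−1)/n_cpg methylation"; a 4-CpG region yields
bins >0%, >25%, >50%, >75%). Tumor-derived fragments form a population with
similar but not identical methylation densities, which these tail fractions
capture well at low dilutions. The `at_or_below` alternative (fraction with
≤ k methylated CpGs, k = 0..n_cpg−1) is the exact elementwise complement of
the default grid and is retained behind a flag because the two phrasings of
the feature appear in different places of the original description; the
operationally unambiguous worked example fixes `or_higher` as the default.
A region with zero retained reads yields a missing (NaN) block, never
zeros; samples with missing blocks are excluded from cohort evaluation with
a logged reason.

## Leave-one-out evaluation harness

For each held-out sample: the training remainder is optionally rebalanced
(binary task only) by a SMOTE-ENN-style resampler — minority oversampling
by convex interpolation between minority nearest neighbours until class
balance, then edited-nearest-neighbour cleaning that drops samples whose
3 nearest neighbours vote against their label (never emptying a class);
candidate models are scored by stratified inner 5-fold cross-validation
under the evaluation metric (mean of per-fold scores — the false-positive
budget of the custom metric applies per fold); the winner refits on the
full remainder and predicts the held-out sample. Everything derives from
one master seed via spawned seed sequences, so runs are exactly
reproducible, and the held-out sample never enters resampling or model
selection (asserted structurally in the tests).

The default candidate pool is small and deterministic: two logistic
regressions (C = 1, C = 0.05) and a 60-tree random forest. The original
workflow used a heavyweight AutoML ensemble; that is intentionally not
replicated — the harness, metric, features and decision rules are the
substance here, the base learner is pluggable.

**Custom metric** (binary task): with FP the misclassified non-cancer
count, the score is `branch_offset + specificity + 0.01·sensitivity` while
FP ≤ `fp_budget` (default 1) and `0.8·sensitivity + 0.2·specificity` after.
Because `branch_offset` (2) exceeds 1 and any weighted combination is ≤ 1,
every within-budget score strictly dominates every over-budget score — a
lexicographic "specificity first" preference in a single scalar. The
transition weights are configurable; the 0.8/0.2 split is this package's
choice of a "heavily sensitivity-weighted" combination.

Multiclass risk scores (per-class probabilities summing to 1) are judged by
best match (arg-max), rank ≤ 2, and within range — every class with score
strictly above 1/k for k categories (1/6 ≈ 0.17 for five tumor types plus
reference). Binary metrics are sensitivity, specificity, balanced accuracy
and midrank AUC; single-class label sets flag AUC as undefined rather than
guessing.

## Synthetic data

`simulate_beta_matrix` draws beta values from a Beta distribution
re-parameterised by (mean, SD) — respecting the bounded scale — with a
clipped-Gaussian fallback where no Beta distribution attains the requested
spread. Planted marker probes put the reference (and normals, and negative
tumor types) at an extreme (default 0.02 or 0.98) with SD 0.01 and shift
the positive tumor types' mean by ±0.5; decoys sit mid-scale (0.5) with SD
0.1 for all groups, so no selection filter should retain them. The default
layout plants 2 detection and 2 class-specific probes per class among 500
probes for 5 classes, 30 reference / 20 tumor / 20 normal samples per
group — desk-scale counts chosen to keep every test seconds-fast while
leaving median estimates tight relative to the planted effects.

`simulate_reads` emulates targeted sequencing of plasma cfDNA: each
molecule is tumor-derived with probability `tumor_fraction`; CpG calls are
independent Bernoulli draws at `tumor_meth` (0.85) or `background_meth`
(0.01); non-CpG conversion failures arrive at `conversion_error` (0.005)
over 20 non-CpG cytosines per read; mean base quality is Gaussian (36 ± 2).
The closed-form dilution law — expected methylated-call fraction
`tf·tumor_meth + (1−tf)·background_meth` — is verified by simulation. An
optional haplotype mode gives every CpG of a tumor molecule one shared
Bernoulli draw, emulating fully concordant methylation haplotypes.
Cohorts derive per-sample seeds from the cohort seed by seed-sequence
spawning.

What the generator does **not** model: fragment-length and coverage
heterogeneity, sequencing error at base level, correlated CpG structure
short of the all-or-nothing haplotype mode, batch effects, age/sex
covariate structure, and any empirical distribution of ctDNA fractions per
cancer type. Passing tests therefore demonstrate the correctness and
internal consistency of the algorithms under their stated assumptions — not
clinical performance on real cohorts, whose headline numbers require the
original external datasets.

## Numerical conventions and degenerate inputs

* All threshold comparisons that award a "signal" bit are strict; boundary
  values side with the null (reference-like, non-tumor) reading.
* Ranks are minimum ranks; tied classes share the best rank.
* Undefined quantities (no coverage, no observations, single-class AUC) are
  flagged or propagated as missing, never coerced to 0.
* Problem sizes in tests and the acceptance script (500-probe matrices,
  30+30-sample cohorts at depth 2000, 5–20 seeds) are the package's chosen
  desk-scale study conditions; they keep estimates well inside the asserted
  tolerances.
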