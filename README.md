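# methylpanel

CpG methylation marker panels for cell-free DNA (cfDNA) liquid biopsy:
marker discovery from beta-value matrices, binarized tumor/normal calling,
tissue-of-origin classification, plasma signal-fraction thresholding,
read-level methylation-density features, and a leave-one-out evaluation
harness — with synthetic-data generators so the whole pipeline is testable
at desk scale.

## Who this is for

Computational epigenomics groups building or auditing small CpG marker
panels for cancer detection from plasma: the package covers the analysis
path from a discovery beta matrix (samples × probes, β ∈ [0, 1]) down to
per-read methylation calls from targeted bisulfite/enzymatic sequencing.

## The method

**Marker selection.** Against a blood reference whose methylation at a
probe is extreme (β ≤ 0.1 or β ≥ 0.9) and stable (SD ≤ 0.07), a
tumor-vs-normal (T-N) marker requires at least one tumor type with
|median β_T − median β_ref| ≥ 0.3 while every normal tissue stays within
0.1 of the reference. Detection panels are greedy set covers giving every
tumor type ≥ 2 detecting probes; classification panels are chosen by
greedy information gain, adding the probe whose binarized per-class profile
most reduces the conditional entropy of the class partition.

**Binarized calling.** A sample's β values binarize against per-probe
cutoffs (midway between the reference extreme and the minimal qualifying
tumor shift; bit 1 = "far from reference", strict comparison). The T-N
call is an OR: tumor iff any bit is 1. Tissue of origin is the arg-min of
the mean Euclidean distance d_c from the sample's bit vector to each
class's training profiles, with three criteria — best match, rank ≤ 2, and
"within range" (all classes with d_c ≤ d_min + δ) — plus QFfit
(training-distance quantile) and naive-Bayes distance adjustments.

**Plasma thresholding.** Around each panel CpG (±200 bp) the methylated /
unmethylated call counts (cm, cu) give a signal fraction
x = cm/(cu+cm) (or cu/(cu+cm) at methylated-reference loci); per-region
thresholds are the maximum x among control plasma samples, and a case is
called tumor iff x strictly exceeds the threshold at any region.

**Read-level features.** After conversion QC (sample fails if non-CpG
methylation > 3%) and read filters (mean quality < 20, > 8 methylated
non-CpG cytosines, < 90% CpG span), each region contributes the cumulative
feature block: the fraction of reads with ≥ k methylated CpGs,
k = 1..n_CpG (a 4-CpG region gives bins >0%, >25%, >50%, >75%). A
leave-one-out harness with inner 5-fold model selection under a
specificity-first metric (specificity is optimized until more than one
non-cancer sample is misclassified, then a 0.8·sens + 0.2·spec
combination) evaluates the features.

## Worked example

```python
import methylpanel as mp

# discovery: simulate a labelled beta matrix, select both panels
cfg = mp.default_beta_config(n_classes=3, n_probes=200, seed=7)
m, ann, truth = mp.simulate_beta_matrix(cfg)
cands = mp.select_tn_candidates(m, ann)
panel = mp.assemble_detection_panel(cands, ["C1", "C2", "C3"])
ccands = mp.select_classification_candidates(m, ann)
cpanel = mp.entropy_panel_search(m, ann, ccands, seed=0)
rep = mp.evaluate_panel(m, ann, cpanel, delta=0.5)

# plasma: simulate a 30+30 cohort, build features, LOO-evaluate
regions = mp.toy_panel_regions(8, 4)
case = mp.ReadSimConfig(regions=regions, depth=2000, tumor_fraction=0.3)
ctrl = mp.ReadSimConfig(regions=regions, depth=2000)
reads, labels = mp.simulate_plasma_cohort(case, ctrl, 30, 30, seed=7)
feats, qc = mp.cohort_feature_table(reads, regions)
ds = mp.CohortDataset.from_table(feats, labels)
preds, loo = mp.loo_evaluate(ds, metric="custom", resample="smote-enn", seed=7)
```

prints (via the corresponding `print` statements):

```
T-N candidates: 12  detection panel: 6 probes
classification panel: 3 probes -> ['cg000009', 'cg000002', 'cg000007']
best-match accuracy: 100%  mean rank: 1.00
LOO sensitivity: 1.00  specificity: 1.00  AUC: 1.000
```

Twelve probes pass the T-N filters (the 12 planted markers; none of the
188 decoys), the greedy cover needs 6 of them to give each of the 3 tumor
types two detecting probes, and 3 entropy-selected probes fully split the
classes, so resubstitution classification is perfect with the true type
always ranked first. On the sequencing side, a 30% tumor fraction at depth
2000 is easily separable: every held-out case scores above every held-out
control, giving sensitivity, specificity and AUC of 1. Lower
`tumor_fraction` or `depth`, or raise `ref_extreme_sd`, to explore the
regimes where these numbers degrade.

A command-line interface mirrors the stages
(`methylpanel simulate|select|sign|classify|plasma-call|features|evaluate|run`);
`methylpanel run --config cfg.json` executes a multi-stage pipeline and
writes a manifest with artifact hashes for reproducibility.

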