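# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limits of `cnacircuits`.

## Coordinate and data conventions

All genomic coordinates are 0-based half-open (BED semantics) everywhere in
memory; BED is read and written natively and any 1-based source must be
converted at the boundary. Expression is kept on its native non-negative
scale (TPM-like for eRNA, FPKM-like for genes); every statistical
comparison operates on log2(x+1). FDR control is Benjamini–Hochberg
throughout.

## Recurrent peak calling

The caller captures the frequency-times-amplitude principle of GISTIC
without a probe-level model. The genome is tiled into fixed bins (default
100 kb); each sample contributes to a bin the length-weighted mean log2
ratio of its covering segments. Per direction, the bin G-score sums the
ratio excess beyond the calling threshold (±0.3, conventional SNP-array
practice) across samples. The null distribution pools bin scores from 1000
independent per-sample, per-chromosome circular shifts of the binned
profiles, which preserves each sample's segment-length structure while
destroying cross-sample recurrence. Empirical upper-tail p-values (with +1
smoothing) are BH-adjusted over all bins; maximal runs of bins with
q ≤ 0.25 become peaks, reported with the full run as the region and the
max-G bin as the summit. There is no broad/focal decomposition, no
arm-level calling, and no analogue of GISTIC's peeled-off confidence
regions; the full significant run is deliberately used because peaks here
only serve to assign enhancer/gene copy status.

Copy status of a feature inside a peak is read from the sample's covering
segment (largest overlap on ties): +1 when the ratio reaches the
amplification threshold in an amplified peak, −1 mirrored for deletions,
0 otherwise. Features outside every peak are dropped — only peak-resident
enhancers are carried downstream.

## Enhancer filtering and target calling

Enhancers overlapping any promoter window (TSS ± 2 kb, strand-aware via
the TSS, symmetric window) or any exon are excluded; the rest are labeled
intronic (inside a gene body) or intergenic. Gene-level TSSs are used;
transcript-level annotation is out of scope.

Candidate targets are all genes whose TSS lies within 1 kb–10 Mb of the
enhancer midpoint (distance measured midpoint→TSS; the nearest candidate
is flagged, ties broken lexicographically on gene id). By default all
candidates in the window are tested (`target_mode: window`); a
nearest-only mode exists because the narrower reading of the procedure is
also defensible. Each (enhancer, gene) pair is tested altered-vs-unaltered
with Welch's t-test — the unequal-variance variant is the robust default
for expression data — and BH runs globally across all tested pairs of one
CNV direction; per-enhancer correction with a handful of candidates would
be anti-conservative. A link requires q < 0.05 *and* a direction-consistent
mean difference. Groups below 3 samples are never tested: t-statistics on
smaller groups are meaningless.

## Motifs, triplets, network

PWM scanning is a standard log-odds scan, log2(p/background) summed over
positions, both strands, with a per-motif threshold of 0.8 × the maximal
attainable score (configurable; no claim of equivalence to any proprietary
scanner's cutoffs). N bases contribute 0 bits. Motif enrichment in
CNV-altered enhancers is a one-sided Fisher exact test on
has-hit × altered/rest counts over the enhancer universe, flagged at
p < 0.005.

A triplet (TF, enhancer, gene) requires the conjunction: the TF's motif is
enriched for the direction *and* present in that enhancer; the
enhancer→gene link exists; both TF and gene are differentially expressed
between tumors and normals (BH FDR < 0.1 and >1.2-fold on linear-scale
means); and TF–gene Spearman correlation exceeds 0.3 in magnitude at
FDR < 0.01. The edge sign is + for concordant dysregulation, − otherwise.
Triplets aggregate into a directed multigraph per CNV direction (one edge
per distinct TF–gene–sign, supporting enhancers kept on the edge;
conflicting signs become parallel edges). The core module keeps TFs with
out-degree >20 and genes with in-degree >7 and the edges between them;
on small synthetic cohorts these paper-scale thresholds prune everything,
which is expected and reported rather than rescaled. The cancer-gene
permutation test draws same-size gene sets without replacement 10,000
times and uses the (1 + hits)/(B + 1) estimator so p is never zero.

## Survival model

The cohort is split 50/50 balanced on gender and age: within each gender,
age-sorted adjacent pairs are split one to each half with random
orientation, so group age means agree within a within-pair difference.
Module genes are screened by univariate Cox on log2(x+1) expression in the
training half (Wald p < 0.05; Efron tie handling via lifelines). The risk
score is the linear combination of screened univariate coefficients — the
coefficients are deliberately not refit jointly by default, because the
score formula indexes the screen's genes, but a penalized joint refit is
available (`joint_refit`). Patients are dichotomized at the training
median (score > threshold → high; at the threshold → low, fixed for
reproducibility), the threshold is frozen for the testing half and any
external cohort, and the groups are compared by log-rank plus a
multivariate Cox adjusted for age, grade, gender and IDH (listwise
deletion of incomplete records, counted in the output).

## The synthetic cohort generator

The generator emulates a multi-grade CNV + expression study: by default
150 tumors (50 per grade II/III/IV) and 5 normals on five 42-Mb
chromosomes carrying 300 enhancers, 500 genes and 12 TFs.

*CNVs.* Twenty 200-kb regions (alternating amplified/deleted) are planted
with carrier prevalence 0.6/0.7/0.8 by grade — prevalence non-decreasing
with grade, matching the heavier CNA burden of high-grade tumors — at mean
log2 ratio ±1. Discrete copy states {0..4} map to segment ratios
log2(c/2) plus Gaussian jitter (sd 0.05), so amplified carriers sit at
state 4 and deleted at state 1. Each sample additionally receives ~3
random passenger events (exponential lengths, mean 2 Mb; ratios ±0.4–1.0)
carved into copy-neutral gaps, giving the permutation null non-trivial
structure. Passengers live only in segment space; expression couples to
the planted peaks, whose per-sample states are recorded in the truth.

*Expression.* Feature expression is baseline × dosage^(c−2) × log-normal
noise (sd 0.25 natural log; dosage factor 2.0). Noise is multiplicative
log-normal because FPKM/TPM values are positive and heavy-tailed; the
neutral limit (dosage 1, zero noise) reproduces baselines exactly. Each
planted peak contains one target gene regulated by two enhancers (40
links); everything else in the peak is gene-free so that the only
dosage-coupled gene near an altered enhancer is its true target — within a
peak the two enhancers and the gene share one alteration pattern, which is
the irreducible confounding of this design. About 30% of ordinary genes
get a random tumor-vs-normal fold (log2 fold ~ N(0,1)); without this
realistic DE landscape a BH screen over ~500 features with 5 normals would
be dominated by the small-sample p-value floor. Circuit TFs are
dysregulated 4-fold in tumors with extra biological variance (log-normal
sd 0.4), and each circuit's target gene is additionally scaled by
(TF deviation)^(±1), giving detectable co-expression of the planted sign.

*Motifs.* Each TF gets a distinct length-10 consensus embedded as a 0.97
point-probability PWM. The circuit's motif is planted once in its circuit
enhancer and in five further CNV-altered enhancers of the same direction
(other peaks) — TF binding is pervasive, and a single planted instance is
statistically undetectable by any count-based enrichment test. Background
sequence is i.i.d. uniform ACGT.

*Survival.* Event times are exponential with log-hazard
Σ_k β_k z_k over six prognostic circuit genes (β = ±0.8 per SD of
log2(x+1) expression), censored by an independent Uniform(0, c) time whose
horizon c is solved numerically so the expected censored fraction matches
the configured 30%. Age, gender and IDH are drawn independently of
outcome.

What the generator does **not** emulate: probe-level SNP-array noise,
tumor purity and subclonality, RNA-seq count sampling, linkage between
clinical covariates and molecular state, transcript isoforms, or realistic
sequence composition. Recovery on these cohorts therefore demonstrates the
correctness of the inference chain under its own assumptions, not
performance on real tumors.

## Determinism and reproducibility

All randomness flows from a single seed through named `SeedSequence`
substreams (carriers, segments, expression, sequences, survival,
clinical), so adding a component never perturbs earlier draws. Pipeline
runs with the same config and seed produce byte-identical artifacts; the
run manifest records the config snapshot, per-stage record counts, version
and seed, and omits wall-clock timestamps unless `record_timestamps` is
set, precisely so that identical runs compare equal byte-for-byte.

## Problem sizes used in the shipped analyses

The shipped tests and the acceptance script use the default strong-effect
study (150 tumors) for recovery, twenty scaled-down null cohorts
(45 tumors, 2 chromosomes, 6 peaks) for false-discovery calibration,
50 (tests) or 20 (script) replicates of an n=300 planted-prognostic cohort
for survival separation, and n=400 for hazard-ratio recovery — sizes at
which every quantity is stable on a single CPU while staying in the regime
the defaults were designed for.
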