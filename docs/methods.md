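# Methods

This note documents the models, estimators and numerical choices behind
`oligohox`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the procedure was genuinely open.

## Gene-body methylation signature

The signature is the unweighted arithmetic mean of three gene-body probe
beta values; the hypermethylation threshold is the midpoint of the
per-group mean signatures for the expression-negative and
expression-positive groups. Midpoints are computed in full precision;
reported values are *truncated* (not rounded) to four decimals, which is the
convention that turns the midpoint 0.35775 of the canonical group means
(0.3034, 0.4121) into the reported 0.3577. The hypermethylation call is
strict (`signature > threshold`); a signature exactly at the threshold is
hypomethylated. Samples missing any of the three probes receive an explicit
missing call, never an imputed one.

Probe screening applies three tests per candidate probe at α = 0.05: the
probe is dichotomized at its cohort median for the Mann-Whitney age test
and the log-rank survival test, and enters as a continuous covariate in a
Cox model adjusting for age and grade. The per-probe median split mirrors
the elevated/low convention used for expression; no published per-probe
thresholds exist, so the choice of the median is recorded in the screening
output metadata. A probe whose median split leaves one group empty (e.g. a
constant probe) fails screening with reason "degenerate".

## Pan-HOX pooling, batch adjustment, consensus stability

Pooling takes the intersection of gene-body probes annotated to HOXA-D
locus genes across all input cohorts; the source cohort becomes the batch
label.

Batch adjustment operates on logit(β) (betas clipped to (1e−6, 1−1e−6), so
a single-batch input round-trips to ≤1e−12). Each batch's per-probe
location effect (deviation of its mean from the grand mean) is removed
exactly; batch scales are equalized to the pooled within-batch variance
through an empirical-Bayes estimate (inverse-gamma moment prior across
probes, ComBat-style). Location effects are deliberately *not* shrunk:
shrinkage leaves each probe's realized sampling noise in the batch means
(residual between-batch differences of 0.01–0.02 beta units in our
measurements, versus ~0.001 with exact removal), and the downstream
stability clustering needs between-batch mean structure gone. The scale
component, where estimation noise rather than realized structure dominates,
is where the EB prior earns its keep. The adjustment assumes batches share
the cluster structure; a protected covariate perfectly confounded with
batch triggers a warning because the adjustment would remove its signal.

Consensus clustering runs `n_runs` independent 2-D UMAP embeddings (random
initialization, seed = base seed + run index; neighbors 15, min_dist 0.1,
both config-exposed and recorded in the result metadata), each partitioned
by k-means with k = 2 and 10 restarts. The embedding partitioner is a
design choice: 2-means is the simplest partitioner consistent with two
separated clusters. Labels are aligned across runs by the agreement-
maximizing mapping (ties broken canonically so alignment is invariant to
flipping either input). The switch frequency is defined against the
per-sample *majority* label over all runs — not against an arbitrary
reference run — which bounds it by 0.5 and makes it reference-free; samples
with switch frequency strictly above 0.10 are excluded. Cluster orientation
is data-determined: HOX-high is the majority group with the greater overall
mean beta.

Differential methylation uses Welch's t per probe on logit(β); the reported
effect is the logit-scale mean difference (the "log fold change" scale for
methylation here, named in output headers), BH-corrected across probes.
Per-gene and per-locus effects are arithmetic means of member-probe
effects. Probes with zero variance in both groups get effect 0 and an
undefined (NaN) p.

## Single-nucleus pipeline

Clustering: library-size normalization to 10,000 counts, log1p, PCA (30
components), k-means (k configurable, default 10). All-zero nuclei are
dropped with a log entry. k-means on PCA is used in place of graph
clustering as the simplest deterministic partitioner adequate for
well-separated nuclear populations.

Arm dosage: meta-cells are seeded random partitions of each cluster into
groups of ≤25 nuclei, averaged on the normalized scale. Per gene we take
log((m + 0.05)/(r + 0.05)) of meta-cell versus reference-mean expression,
restricted to genes with reference mean ≥ 2 normalized units (near-zero
denominators carry no dosage information), clipped to ±1.5. Three
corrections stabilize the zero point, in this order: (1) per-gene anchoring
on the reference meta-cells' mean log-ratio, cancelling pseudocount and
composition biases; (2) per-meta-cell median centering, removing the global
inflation that library-size normalization induces in dosage-altered cells;
(3) after smoothing (centered moving average of 51 genes in genomic order,
run *per arm* so windows never straddle a centromere; shrunk with a log
entry on shorter arms) and arm averaging, per-meta-cell recentering on the
median arm score, which assumes most arms are copy-neutral — the standard
CNV-caller assumption. Calls use a symmetric threshold τ = 0.15 natural-log
units: loss < −τ, gain > +τ, intact otherwise. On synthetic data with
planted dosage 0.5 and ≥150 genes per arm this recovers arm log-ratios
within ±0.05 of log 0.5.

Compartments: a meta-cell is codeleted when 1p and 19q are called loss and
1q and 19p intact. "Universal" codeletion is operationalized as ≥95% of a
cluster's meta-cells (config `universality`); ≤5% makes the cluster
non-neoplastic, anything between is excluded. The reference for dosage
inference starts from marker-typed clusters (suspected non-neoplastic) and
is updated exactly once to the clusters the first pass called
non-neoplastic; a single update round is recorded rather than iterating to
an unspecified convergence rule.

Cell typing scores each cluster's marker panels (neurons RBFOX3;
oligodendrocytes MBP/MOG/CNP; astrocytes SLC1A2/GFAP/AQP4/ALDH1L1;
microglia PTPRC/CD163/CD14) as the mean per-gene scaled deviation of the
cluster mean from the overall mean, scaling by the nucleus-level sd so
near-flat genes cannot dominate; the top panel must beat the runner-up by a
margin (default 0.25 sd) or the cluster is unassigned. Missing markers are
logged, not fatal.

Program scores follow the bin-matched control-gene scheme: genes are ranked
into 25 equal-occupancy bins of aggregate expression; for each program gene
100 control genes are drawn (with replacement) from its bin; the score is
the mean centered expression of program genes minus that of the controls
(centering = per-gene mean across nuclei). The permutation null draws
random gene sets matched in size and bin composition, scored identically
(implemented with multinomial count weights per bin, so sampling is exact
but vectorized). p = (1 + #{null ≥ obs}) / (1 + n_perm): the add-one
estimator never returns 0 and its floor is 1/(n_perm+1) ≈ 1e−5 at the
default 100,000 permutations. FDR is BH over the full nucleus × state grid.
A nucleus is assigned the argmin-FDR state when that FDR < 0.0125
(0.05 / 4 states), else "gradient"; FDR ties break by the larger observed
score, then the fixed order OPC-like, Astro-like, Cycling, RE. RE nuclei
stay assigned but are flagged for exclusion from downstream contrasts when
fewer than 30 exist (config `min_state_count`). Stemness and OC/AC lineage
scores are the same relative score with their own gene sets; the lineage
differential OC − AC is reported alongside.

Sparse-marker prevalence contrasts are 2×2 Fisher tests on the fraction of
nuclei with any nonzero marker count; score contrasts are two-sample t.

## Cohort statistics

Log-rank and Cox fits delegate to lifelines (Efron tie handling, the
standard choice when ties are frequent). Collinearity is screened before a
Cox fit by iteratively dropping the covariate with the largest VIF until
all VIFs ≤ 10; VIFs come from auxiliary OLS regressions with intercept, and
dropped covariates are reported with the VIF they had at removal. The
two-sided Fisher p is the enumeration definition (sum of probabilities of
margin-preserving tables no more probable than the observed), which scipy
implements and the test suite verifies exhaustively against a brute-force
enumeration for small tables. Mann-Whitney uses the exact null below 25
per-sample observations when there are no ties, the tie-corrected normal
approximation otherwise. BH adjustment passes NaNs through untouched.

The dip statistic for unimodality is computed in-package from the GCM/LCM
construction — for each candidate mode, the distance of the empirical CDF
from the convex cone on the left (half the maximal gap to the greatest
convex minorant) and from the concave cone on the right, minimized over
modes — with a Monte-Carlo p-value against uniform samples of the same size
(default 200 draws, cached per size). The Monte-Carlo calibration makes the
test exact for the statistic as implemented.

The adjuvant-therapy cutoff of "8 months" is fixed at 244 days
(8 × 30.5, config-overridable and logged); whether the original rule used
days or calendar months is not determinable, so the constant is explicit.
A patient with neither a regimen label nor a start day stays unlabeled
rather than defaulting to False.

## Synthetic-data generator

The generator is the package's study-conditions stand-in, not a tuning
surface. All draws come from `numpy.random.default_rng(seed)` (PCG64), so
identical truth objects give byte-identical output across platforms.

*Bulk cohort*: patient age is a two-component normal mixture (means 38/55,
sd 7, younger weight 0.55, clipped to 18–90) reflecting the bimodal age
structure of the disease; positive status follows a logistic link in age
(slope 0.12/yr, centered near 47) so prevalence rises with age; the three
signature probes draw from Beta distributions parameterized by
(mean, concentration) with group means 0.3034/0.4121 — the canonical
values — and concentration 50, a free parameter documented rather than
fitted since no published dispersion exists; 5 of the 11 flanking probes
get a weak 0.02 shift and 6 none. Expression is exactly 0 TPM for
negatives (log-normal for positives), which makes the cohort median zero
whenever positives are a minority, as in the emulated cohorts. Survival is
exponential with planted hazard ratio 9.3 and baseline hazard 0.0287/yr
(positive-group median ≈ 2.6 years), censored administratively at 15 years
— long oligodendroglioma follow-up without a dropout model.

*Pan-HOX*: 422 gene-body probes cycling over the four HOX loci; two
clusters separated by a beta-scale offset concentrated on HOXD probes
(×1.5) but present elsewhere (×0.85); optional additive logit-scale batch
offsets; a configurable fraction of ambiguous samples sits exactly midway
between the cluster means. Default batch sizes 171/170/24 match the pooled
cohort structure the pipeline targets.

*Single-nucleus*: negative-binomial counts (dispersion 0.5, the simplest
overdispersed model consistent with snRNA-seq) with mean depth 4000 over
~2100 genes: 250 genes on each of 1p/1q/19p/19q, 1200 background genes
spread over eight neutral arms (keeping the 1p/19q transcriptome share
realistic), plus marker, program and lineage genes on neutral arms. Every
cell type carries a broad log-normal expression signature over background
genes (sd 0.4), as real brain cell types do, so clustering does not hinge
on a handful of markers. Neoplastic nuclei scale all 1p/19q genes by the
planted dosage (default 0.5) before sampling; state programs upregulate
their 30-gene sets ×4; the sparse marker (the HOXD12 stand-in) is emitted
separately as Bernoulli activity with state-specific probabilities
(Cycling 0.15, OPC-like 0.08, others 0.02, non-neoplastic 0.005) so
prevalence tests are exact.

What the generator does **not** emulate: probe-level spatial correlation
along the genome, array normalization artifacts, IDAT-level noise,
cell-cycle continuums (states are discrete), ambient RNA, doublets, and
batch structure in the single-nucleus data. Passing tests therefore
demonstrate that the estimators recover planted structure under clean
generative assumptions — not that they are robust to every artifact of
real arrays or droplet chemistry.

## Problem sizes used in the test suite

The suite exercises the pipeline at sizes chosen to make planted effects
unambiguous while keeping runs comfortable on one CPU: bulk cohorts of
500–5000 patients, pan-HOX consensus at 300 samples × 422 probes with 25
runs (the full 1000-run protocol is configuration, not code), single-
nucleus datasets of ~1500 nuclei × ~2100 genes with 1500–2000 permutations
(the 100,000-permutation default changes only the attainable p-value
floor), and 200 replicate cohorts of n = 1000 for Cox coverage.

## Known limitations

Batch adjustment assumes shared cluster structure across batches and will
absorb real biology confounded with batch. The consensus procedure is
specified for exactly two clusters. The arm-dosage caller has no HMM
segmentation and assumes most arms are copy-neutral for its recentering;
focal events within an arm are diluted. Cell-state assignment treats
programs as independent hypotheses per nucleus; correlated programs share
control-gene bins but not a joint null. The dip p-value is calibrated
against a uniform null, the conventional but conservative reference.
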