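# Methods

`ctpipe` implements a voxel-level connectome–transcriptome association
workflow for case–control resting-state fMRI studies with two patient
subgroups, together with a seeded synthetic-data generator that stands in
for restricted subject-level data and for multi-donor brain expression
atlases. This note documents the statistical model at each stage, the
parameters that matter, and the design choices made where the method left
room.

## Brain-wide association (bwas)

Functional connectivity between voxels *i* and *j* is the Pearson
correlation of their BOLD time series, variance-stabilized by Fisher's
transform z = atanh(r). For each unordered voxel pair, subject-level z
values are compared between two groups with a two-sided pooled-variance
t-test. Nuisance covariates (age, education, total intracranial volume,
framewise displacement by default) are removed by residualizing the z
values against the covariate design — intercept included, fit jointly
across both groups — before the test; the t degrees of freedom are reduced
by the number of covariates (df = n_a + n_b − 2 − k). Residualizing per
link across all subjects jointly, rather than per voxel time series, is a
design choice: it keeps the nuisance model linear in exactly the quantity
being tested.

Family-wise error control over the link family defaults to Bonferroni on
the unique-pair count n(n−1)/2 at family α = 0.01. Published BWAS work
sometimes quotes the n²/2 convention for the family size and derives the
link threshold from Gaussian-random-field theory; both conventions are
computable via `link_count`, and an externally derived threshold can be
installed verbatim with the `fixed_p` method. The MA statistic of voxel
*i* is the count of links incident to *i* with p below the corrected
link threshold — a nonnegative integer in [0, V−1].

Regions of interest are connected components (26-connectivity by default,
6 optional) of the voxel set with MA strictly above a threshold, retained
when their size is strictly above a minimum (the reference operating point
for full-brain data is MA > 40, size > 100; the demo uses 5/5 because its
brain has 150 voxels). Each ROI reports size, peak MA, peak MNI
coordinate (ties broken at the lowest linear grid index), and majority
atlas label (ties broken by the peak voxel's label); ROIs are ordered by
decreasing size.

## Classification (classify)

Features are Fisher-z correlations between ROI-mean time series, one per
unordered ROI pair (k(k−1)/2 features for k ROIs). Classification is
linear — LDA or linear SVM — after per-feature standardization and
dimensionality reduction (PCA keeping 90 % of training-fold variance, or
linear-SVM RFE halving to 20 features). Evaluation is leave-one-out
cross-validation with the scaler, reducer, and classifier all re-fit
inside each training fold; the held-out subject contributes one signed
decision score. Accuracy/sensitivity/specificity use threshold 0 on that
score; AUC is the rank (Mann–Whitney) statistic on the held-out scores
with ties counted ½. LDA switches to `lsqr` with automatic shrinkage
whenever features ≥ training subjects, which the 253-feature regime
requires. The reported weight vector comes from a final all-subject fit
back-projected to the original feature space (PCA) or zero-padded (RFE).

Which reducer fed which classifier was an open pairing; the default is
PCA→LDA and RFE→SVM, both configurable.

## Clinical statistics (clinstats)

`anova_from_summary` and `ttest_from_summary` recompute one-way ANOVA F
and pooled-variance two-sample t from per-group (n, mean, SD) triples, so
published demographics tables can be verified without subject data. The
t direction is b − a in call order. FC–symptom association regresses the
clinical score on each ROI-pair feature (OLS; slope, Pearson r, two-sided
p) and applies Benjamini–Hochberg FDR across all non-degenerate features
of the run; constant features are flagged and excluded from the FDR
family. The regression direction (score ~ FC) is a convention — r and its
sign are symmetric in the two variables. Within-patient-group regression
is the default, matching how deficit-symptom severity is normally related
to connectivity within the affected group.

## Expression preprocessing (ahba)

The probe-to-region chain is fixed: intensity filter → RNA-seq presence →
RNA-seq concordance → representative probe → scaled robust sigmoid →
region aggregation → differential stability. Gene counts can only shrink
along it.

* **Intensity filter**: a probe survives if it is above background in at
  least 50 % of samples pooled across donors (≥, so exactly half
  survives); a per-donor mode is available.
* **Concordance filter**: Spearman ρ between the probe's microarray
  profile and its gene's RNA-seq profile, pooled over matched samples
  across donors; probes with ρ < 0.2, genes absent from RNA-seq, or fewer
  than 3 matched samples are dropped.
* **Representative probe**: per gene, the surviving probe with highest ρ;
  ties break to higher mean expression, then lexicographic probe id.
* **SRS normalization** (per gene, per donor):
  x′ = 1/(1 + exp(−(x − median)/(IQR/1.35))), rescaled to [0, 1]. It is
  strictly monotone and invariant to affine rescaling of the input. Zero
  IQR falls back to SD scaling; a constant vector maps to 0.5.
* **Region aggregation**: a sample is assigned to the region of its
  nearest labeled voxel center within a cutoff (2 mm beyond the voxel
  size by default); region expression is the mean over assigned samples,
  and unsampled regions are omitted.
* **Differential stability**: per gene, the mean over donor pairs of the
  Spearman correlation of regional profiles across the regions the pair
  shares (pairs sharing < 3 regions are skipped). Genes with DSS
  strictly above 0.5 are retained, per parcellation.

## Consensus co-expression networks (wgcna)

Expression is z-scored per gene; the signed adjacency is
a_ij = ((1 + cor)/2)^β and the topological overlap is
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij). The soft
power β is the smallest candidate whose connectivity distribution fits a
power law with R² ≥ 0.8 and negative slope, defaulting to 12 (the signed
convention) when none qualifies. The consensus TOM across input matrices
is the element-wise minimum after matching each TOM's 95th-percentile to
the first input's. Modules come from average-linkage clustering of
1 − consensusTOM cut at 0.99 × the maximum merge height — the fixed-height
variant of dynamic tree cut; an absolute cut at 0.99 would leave planted
modules merged because between-module dissimilarities on consensus TOMs
sit near 0.97. Clusters with fewer than `min_module_size` genes (50 at
reference scale, 30 in the demo where only ~120 genes survive DSS) are
unassigned (module 0); retention is ≥, so a module of exactly the minimum
size survives. The module eigengene is the unit-norm first left singular
vector of the standardized module submatrix, sign-aligned so its mean
correlation with member genes is positive; variance explained is
s₁²/Σs².

Because the DSS filter is parcellation-specific, the consensus network is
built over the union of the per-parcellation retained genes, and each
parcellation then contributes only its own retained members of a module
to eigengene computation and gene-set derivation. This keeps the
cross-parcellation intersection meaningful instead of circular.

## Transcription–neuroimaging association (assoc)

Each tissue sample receives the mean MA inside spheres of radius 4, 6,
and 8 mm around its MNI coordinate (missing when no voxel center falls
inside; such samples are dropped pairwise per radius). Module eigengenes
are Pearson-correlated with these profiles across samples; BH-FDR runs
across modules within each radius (and parcellation), and a module passes
only when q < 0.05 at *all* radii with one consistent correlation sign —
the sign requirement is added because it defines set membership, and a
mixed-sign module would be unassignable. Genes of passing positive
(negative) modules form the per-parcellation positive (negative) sets;
the condition's final sets are the strict intersection across
parcellations, then intersected with a disease gene list. Overlap between
conditions is the signed set intersection plus a containment report. Key
genes are set members with at least one partner whose pairwise Pearson r
strictly exceeds 0.7 across samples (a mean-r variant and an |r| variant
are exposed). Over-representation of a query set in annotation terms uses
the one-sided hypergeometric tail with BH correction and Haldane-corrected
odds ratios.

## Synthetic study (synth)

The generator produces the statistical structure every stage assumes,
not realistic physiology (no hemodynamics, motion, scanner noise spectra,
or cortical geometry).

**BOLD cohort.** Subjects are drawn as multivariate Gaussian time series
with a per-group target correlation matrix: identity plus planted links
set to base_r + Δr(group). Only second-order structure matters to any
downstream stage, so this suffices. A slightly indefinite target is
projected to the nearest PSD matrix by eigenvalue clipping; if the
projection moves a planted entry by more than 0.05 the offending links
are reported as infeasible. Covariates are Gaussian with per-group
means/SDs emulating a mid-life, all-male clinical cohort (an optional sex
covariate exists but is off by default). The demo brain is 150 voxels at
6 mm (a 36×30×30 mm box): with the analysis spheres fixed at 4–8 mm, a
3 mm mini-brain would be smaller than the spheres themselves. Planted
connectivity lives in equicorrelated voxel blocks, each spanning two
spatially separated slabs so that the effect appears in *cross*-ROI
connectivity; two blocks are shared between patient groups and one is
NDS-specific and placed between the shared ones, keeping both contrast
maps on one large-scale spatial gradient.

**Clinical scores.** The primary score is group mean + coupling ×
(per-subject mean planted-link FC) + Gaussian noise; other scales are
independent group-level noise. The default coupling (−20 with unit
noise) plants a moderate negative FC–symptom correlation (|r| ≈ 0.4–0.5
at n = 40), comparable to a clearly detectable clinical association;
Fisher-z features have sampling SD ≈ 1/√(T−3), which is why the
coefficient looks large.

**Donor expression.** Six donors, 200 samples each (≈1200 pooled,
matching the density of real multi-donor atlases — at 60/donor the
region means are dominated by within-region sampling noise and
differential stability cannot separate planted from null genes). Sample
coordinates are uniform in the MA-map bounding box. Coupled genes follow
sign × 0.9 × (standardized sphere-mean MA at 14 mm) + √(1−0.9²) × GP
field + 0.1 × noise; null genes are pure GP fields (squared-exponential
kernel, 8 mm length scale) — the 14 mm coupling radius encodes that
expression tracks the regional-scale pathology gradient rather than
voxel-sharp MA, which is what makes coupled genes differentially stable
at region resolution. Probe effects add per-probe offsets and 0.1 noise;
a configurable fraction of probes is built to fail the intensity filter
(above-background probability 0.2) and another to fail concordance
(deviations mirrored about the probe baseline, giving strongly negative
ρ); corruption never touches the only clean probe of a coupled gene. The
RNA-seq companion is the gene-level signal plus small noise, with a small
fraction of null genes absent from it.

All randomness derives from one master seed through named CRC32-keyed
substreams, so every artifact is bit-identical across runs and individual
stages can be regenerated independently.

## What the demo does and does not show

The demo (150 voxels, 40/40/40 subjects, 300 genes, 2 planted modules of
60) completes in well under a minute on one CPU and recovers: 4 DS and 2
NDS ROIs, perfect LOOCV separation (the planted effect is 8σ per
feature — by construction, not a claim about real cohorts), significant
negative FC–SDS regressions, 120/120 DSS-stable planted genes, two
consensus modules of exactly the planted memberships, and signed gene
sets with sensitivity 1.0 and false-inclusion 0. Passing these checks
shows the chain is implemented correctly and calibrated under its own
assumptions; it says nothing about effect sizes, artifacts, or
generalization in real fMRI or donor-expression data, and printed
clinical classification metrics from real cohorts are deliberately not
reproduction targets.

## Numerical details and limitations

* Correlations at ±1 are clipped to ±(1−10⁻¹²) before atanh.
* Zero-variance voxel series are rejected at validation rather than
  propagating NaNs.
* Spearman ties use average ranks throughout.
* The hypergeometric test treats term genes outside the universe as
  absent.
* Sphere sampling is O(samples × voxels) by brute-force distances —
  adequate far beyond demo scale, but not for 10⁵-voxel full brains.
* The pooled t assumes equal group variances (validated against the
  published three-group table); Welch is not currently wired through the
  pipeline config.
* One printed summary-table t value is reproducible only in magnitude;
  its sign contradicts the direction convention implied by the other
  rows of the same table, so the package reports the signed value under
  its own fixed b − a convention.
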