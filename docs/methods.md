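# Methods

This note documents the models, conventions and defaults behind each stage of
the pipeline, the design choices made where the underlying protocol left the
design open, and what the synthetic data do and do not establish about real
DCE-MRI.

## Data model

A DCE acquisition is four fat-suppressed T1-weighted volumes: pre-contrast t1
and post-contrast t2, t3, t4 at 0, 1, 2 and 6 minutes (configurable). Signal
is in arbitrary units; every downstream quantity is a ratio or difference, so
only relative signal matters (the rate-in map additionally divides by elapsed
minutes, which is what distinguishes it from the PE numerator). Arrays are
index-space (x, y, z, t); world orientation lives in the NIfTI headers.

## Synthetic phantoms

The phantom emulates a unilateral fat-suppressed acquisition:

* **Geometry.** Half-ellipsoid breast whose flat face (z = 0) is the chest
  wall; spherical tumor strictly inside; parenchyma is a scaled concentric
  half-ellipsoid core whose scale is found by bisection on voxel counts so
  the parenchymal fraction of the breast hits the requested value (default
  0.20) up to grid discretization. Defaults: 64×64×40 grid at 1.5 mm,
  breast radii 42 mm, tumor radius 8 mm.
* **Kinetics.** Per-compartment signal courses at t1..t4 — adipose
  (30, 33, 35, 36): dark and barely enhancing, as suppressed fat; parenchyma
  (100, 180, 200, 190): moderate enhancement with mild washout (PE = 100,
  SER = 10/9 exactly); tumor (100, 250, 300, 280): fast enhancement with
  washout (PE = 200, SER = 10/9). With zero noise these closed forms are
  exact, which makes the phantom the analytic oracle for the kinetics stage.
* **BPE heterogeneity.** The parenchymal enhancement *amplitude* is modulated
  by 1 + f(x), where f is white Gaussian noise smoothed with a Gaussian
  kernel of 4 mm correlation length and rescaled to a target variance over
  parenchymal voxels. The class presets are variance 0.09 for TN and 0.01
  for non-TN phantoms — free knobs, since no quantitative field model of real
  BPE is available; they are chosen so the between-class texture contrast is
  clearly detectable at the default additive noise (SD 5 signal units)
  without being trivially separable at the single-voxel level.
* **Determinism.** All randomness comes from one generator seeded by the
  spec; masks are purely geometric, so two seeds share masks and differ only
  in field and noise realizations.

## Synthetic feature tables

Each block (clinical: 5, density: 1, tumor texture: 39, BPE texture: 39
columns, named as a study export would name them, e.g. "parenchyma SER
skewness") is a unit-variance equicorrelated Gaussian with a class-dependent
mean shift applied to every column: x = √ρ·g + √(1−ρ)·ε + d·y. Defaults:
88 cases, exactly 11 positive ("fixed" label mode; a binomial mode exists for
larger cohorts), d = 1.5 for BPE columns, 0.6 for tumor/clinical columns,
0.3 for density, ρ = 0.5 within texture blocks (real radiomic features are
strongly inter-correlated), 0.1 for clinical. The planted structure makes the
discriminative value of each block known by construction: the BPE block
carries most of the class signal, the tumor block a weaker share — the
contrast the classification stage must detect.

What the generators do **not** model: MR physics (no coil/bias field, no T1
mapping), breathing or motion, non-mass lesion morphologies, real covariance
structure between texture features (equicorrelation is a deliberate
simplification), and categorical clinical readings (clinical columns are
continuous here). Passing tests therefore establish the correctness and
honesty of the *computational chain*, not clinical performance on patients.

## Segmentation

* **Breast.** The skin edge is found by thresholding the t3 (peak
  enhancement) volume. The automatic threshold is the *lowest* of the two
  3-class multi-Otsu thresholds: a fat-suppressed breast histogram is roughly
  three-class (air, suppressed fat, enhancing tissue), and the skin edge is
  the air/tissue boundary; a single Otsu threshold tends to land between fat
  and gland and would discard the adipose compartment. Plain Otsu is the
  fallback for volumes with too few distinct values. The thresholded
  foreground keeps its largest 26-connected component and is morphologically
  closed (ball radius 2, with edge-replicating padding so tissue touching the
  grid boundary is not eroded). The chest wall — an interactive step in
  clinical workflows — is an explicit input: an exclusion mask or a
  half-space such as `plane:z<5`, so runs are scriptable and reproducible.
* **Tumor.** Seeded 3-D region growing: the maximal 26-connected component of
  the voxels whose t3 intensity lies in a caller-given band and that contains
  the seed. A seed outside the band is an error; a region touching the volume
  boundary raises a warning. Manual corrections are XOR patches.
* **Parenchyma/adipose.** Two-class fuzzy c-means on pre-contrast (t1)
  intensities of the breast-minus-tumor voxels; fuzzifier m = 2, tolerance
  1e-5 on centroid movement, max 300 iterations, k-means++-style seeded
  initialization. Each voxel goes to its larger-membership class. Which class
  is parenchyma is configurable (`parenchyma_is = brighter|darker` on t1);
  the default is *brighter*, since on fat-suppressed T1 fibroglandular tissue
  is typically brighter than suppressed fat.
* **Density.** 100·|parenchyma|/|breast| in voxel counts (spacing cancels on
  a uniform grid).

## Kinetic maps

"Maximum" always means the maximum over the post-contrast timepoints t2..t4 —
the baseline is excluded, so flat or decreasing courses give PE ≤ 0 rather
than 0/0, and rate-in is negative when the signal never exceeds baseline.
Rate-in is normalized by elapsed minutes to its peak. Voxels whose PE
denominator (baseline < 1 signal unit) or SER denominator (|S_t4 − S_t1| <
1 signal unit) is too small are flagged invalid and *excluded* from texture
statistics, never imputed. SER = 1 exactly whenever the course peaks at t4;
SER > 1 indicates washout.

## Texture

Thirteen features per map per compartment (39 per compartment):

* First order: sample mean, SD (n−1), Fisher skewness g1, excess kurtosis g2.
  Moments needing more samples than available — or undefined on a constant
  sample — are reported missing (NaN), not zero.
* GLCM: the map is uniformly re-quantized to G = 8 levels between the min and
  max of the compartment's valid voxels (per-region bounds, so features are
  invariant to any strictly increasing affine rescaling of the map). Pair
  counts are accumulated per direction for all 26 unit offsets, normalized to
  p(i,j), features computed per direction, then averaged over directions with
  at least one valid pair (empty directions are dropped, not counted as 0).
  Counts are not symmetrized per direction; averaging over all 26 directions
  covers both orientations. Formulas (natural-log entropy; μx, μy, σx, σy the
  marginal moments; μ = (μx+μy)/2):
  energy Σp², contrast Σ|i−j|p, correlation Σ(i−μx)(j−μy)p/(σxσy) (defined 0
  when σxσy = 0), variance Σ(i−μ)²p, homogeneity Σp/(1+|i−j|), sum mean
  ½Σ(i+j)p, entropy −Σp ln p, inertia Σ(i−j)²p, cluster shade
  Σ(i+j−μx−μy)³p.
* **Contrast vs inertia.** In Haralick's original feature set these two
  coincide. To keep nine distinct features, *inertia* keeps the classic
  squared-difference form and *contrast* uses the absolute-difference
  (dissimilarity) form. Both are exported; anyone comparing against a
  toolbox that uses the squared form for "contrast" should read this
  package's *inertia* column.

The engine is verified against an independent brute-force pair enumerator
(plain Python loops over all voxel pairs, features recomputed from a count
dictionary) to 1e-10 on randomly masked volumes.

## Supervised modeling

Within **every training fold** of a stratified 10-fold cross-validation,
repeated 10 times with freshly drawn partitions:

1. Features are ranked by the Pearson χ² statistic of the feature-bin × class
   contingency table, after equal-frequency discretization into 10 bins
   (columns with ≤ 10 distinct values use their values as bins). The top 30
   (`rank_keep`) survive.
2. SFFS grows a subset: forward-add the candidate maximizing the criterion;
   after each addition, repeatedly backward-remove any feature whose
   exclusion beats the best score previously recorded at the smaller size
   (the just-added feature is exempt). The criterion is the mean held-out AUC
   of the linear SVM under 5-fold stratified CV *on the training split only*.
   Search stops at `sffs_max_size` (10) or when no addition improves; the
   best-scoring subset found is returned (smallest on ties).
3. A linear C-SVC (C = 1) is trained on the standardized selected features
   (standardization statistics from the training fold) and scored on the
   held-out fold: class predictions at the decision boundary give accuracy /
   sensitivity / specificity; raw decision values give AUC (no probability
   calibration).

Summaries are means over all repetition × fold values; 95% CIs are
percentiles of the repetition means. Selection frequency is the percentage of
all folds in which a feature was chosen (reports display features above a
50% floor). Two runs that share a seed share partitions exactly, so their
per-fold metrics pair; `compare_models` applies the two-sided Wilcoxon
signed-rank test to the paired values — an exact sign-flip distribution
(dynamic programming over doubled midranks) for ≤ 25 non-zero pairs, the
normal approximation with tie correction otherwise, and p = 1 when all
differences are zero.

Numerical/performance choices: the inner SFFS criterion calls the low-level
libsvm binding (the same C-SVC solver behind the public estimator) because
per-call input validation would otherwise dominate runtime at n ≈ 80; its
decision values are asserted equal to `SVC.decision_function` in the test
suite. AUC uses the Mann-Whitney rank statistic with midranks. All partition
and selection randomness derives from the single config seed; results are
bit-reproducible.

The no-leakage property is tested directly: with permuted labels the mean
cross-validated AUC stays in [0.40, 0.60]. This canary is the reason both
selection steps live inside the fold — selecting features on the full table
first would inflate AUC well above chance even under the null.

## Clustering

BPE texture columns are standardized to z-scores across cases (sample n−1
SD; zero-variance columns dropped), then partitioned by Lloyd's k-means with
k = 2, Euclidean distance, k-means++ initialization and the best of 50
restarts by inertia. The composition report counts positives per partition;
the "enriched" partition is the one with the larger positive fraction
(invariant to index swaps), and a Fisher exact p-value is attached as
descriptive output only.

## Problem sizes

Defaults used by the test suite and the acceptance script: 88-case tables
with 11 positives; 64×64×40 phantoms (40×40×26 where many phantoms are
generated); 10 CV repetitions for single-table runs and 2 repetitions per
seed where a claim is evaluated across 10 generator seeds; 20 seeds for the
clustering and texture-ordering Monte-Carlo checks; 100 (suite) / 20
(acceptance script) random 6×6×6 volumes for the GLCM brute-force
cross-check. These sizes give stable Monte-Carlo margins while keeping a full
run in the minutes range.

## Known limitations

* The synthetic table's equicorrelated Gaussian blocks understate the messy
  covariance of real radiomic features; absolute AUC values on synthetic data
  are not clinical estimates, only checks of the planted ordering.
* The tumor-only model's cross-validated AUC is high-variance at 11 positives
  (roughly 0.47–0.75 across generator seeds at the default effect sizes);
  claims about it are therefore evaluated as paired contrasts across seeds,
  never as point values.
* Fuzzy c-means on intensity alone assumes a bimodal pre-contrast histogram;
  partial-volume voxels between fat and gland are assigned to the nearer
  centroid with no spatial regularization.
* The GLCM "contrast" naming caveat above matters when comparing to other
  toolboxes.
* Only binary TN-vs-comparator tasks are supported (comparator = a row
  filter on subtype columns); no multi-class subtyping, nonlinear kernels,
  DICOM ingestion or bilateral-breast handling.
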