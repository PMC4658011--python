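# radbpe

Radiomic analysis of breast DCE-MRI that combines features of the tumor with
texture of the surrounding **background parenchymal enhancement (BPE)** to
discriminate **triple-negative (TN)** breast cancer from other molecular
subtypes.

Triple-negative tumors lack ER, PR and HER2 expression, respond to no targeted
therapy, and carry the worst prognosis — so a non-invasive imaging marker is
valuable. Beyond the tumor itself, the enhancement of normal fibroglandular
tissue (BPE) reflects the hormonal and micro-environmental state of the
breast, and its *spatial heterogeneity* turns out to be strongly associated
with TN status. This package implements the full analysis chain needed to test
that association, end to end and reproducibly:

1. **Segmentation** — skin-edge thresholding + largest connected component for
   the breast, seeded 3-D region growing within a gray-level band for the
   tumor, and two-class fuzzy c-means on pre-contrast intensity for the
   parenchyma/adipose split; volumetric breast density = |parenchyma|/|breast|.
2. **Pharmacokinetic maps** from the 4-timepoint signal S(t1..t4)
   (t1 pre-contrast; times 0, 1, 2, 6 min):
   * rate-in = (S_max − S_t1)/(t_max − t1)   (S_max over t2..t4)
   * PE = 100·(S_max − S_t1)/S_t1
   * SER = (S_max − S_t1)/(S_t4 − S_t1)   (SER > 1 ⇔ washout)
3. **Texture** — per compartment and per map, 4 first-order statistics (mean,
   SD, skewness, kurtosis) and 9 gray-level co-occurrence (GLCM) features
   (energy, contrast, correlation, variance, homogeneity, sum mean, entropy,
   inertia, cluster shade), computed in 3-D at a 1-voxel offset, averaged over
   all 26 directions after 8-level re-quantization: 39 features per
   compartment, 78 per lesion.
4. **Supervised modeling** — χ² feature ranking + sequential forward floating
   selection (SFFS) + linear SVM, with both selection steps *encapsulated
   inside every training fold* of a 10×-repeated stratified 10-fold
   cross-validation; metrics are accuracy, sensitivity, specificity and AUC,
   and paired models are compared by the two-sided Wilcoxon signed-rank test.
5. **Unsupervised clustering** — z-scored BPE texture features, k-means
   (k = 2, 50 restarts), and the subtype composition of the two partitions.

Patient data are replaced by a first-class synthetic-data module: 4-D DCE
phantoms (half-ellipsoid breast, spherical tumor, parenchymal core) with known
kinetics and a class-dependent Gaussian-random-field BPE heterogeneity, plus
labeled feature tables with known block-wise effect sizes that mimic the
layout of a radiomic study export (88 lesions, 11 TN by default).

## Worked example

```python
import radbpe as rb

# a synthetic analog of an 88-lesion study table (11 triple-negative)
table = rb.generate_feature_table(rb.FeatureTableSpec(seed=1))

cfg = rb.CvConfig(seed=1)              # 10 x stratified 10-fold CV
tumor = rb.run_nested_cv(table, cfg, scope="tumor")
both  = rb.run_nested_cv(table, cfg, scope="tumor+bpe")
print(round(tumor.summary()["auc"]["mean"], 3))   # 0.7
print(round(both.summary()["auc"]["mean"], 3))    # 0.869
print(rb.compare_models(tumor, both)["auc"] < 0.01)  # True

_, comp = rb.cluster_bpe(table, restarts=50, seed=1)
print(comp["positives_in_enriched"], "of", comp["total_positives"])  # 10 of 11
```

Adding BPE texture lifts the cross-validated AUC from 0.70 to 0.869 — a
significant improvement by the paired Wilcoxon test — and 10 of the 11 TN
cases fall into one k-means partition on BPE texture alone. Both numbers are
what the planted effect structure (standardized mean difference 1.5 in the
BPE block vs 0.6 in the tumor block) should produce: the BPE block carries
most of the class signal.

The same stages run from the shell:

```bash
radbpe simulate table --seed 1 --out table.csv
radbpe classify --table table.csv --scope both --seed 1 --out results/
radbpe cluster  --table table.csv --seed 1 --out cluster/
radbpe simulate phantom --seed 1 --out phantom/
radbpe segment --in phantom/volume.nii --seed-point 31,31,14 --band 250,350 --out seg/
```

## Layout

```
src/radbpe/
  phantom.py       4-D DCE phantom generator (ground-truth masks + kinetics)
  tables.py        feature-table container + synthetic table generator
  segmentation.py  breast / tumor / parenchyma / adipose segmentation
  kinetics.py      rate-in, PE, SER parametric maps
  texture.py       first-order + 26-direction 3-D GLCM features
  modeling.py      χ² ranking, SFFS, nested CV, Wilcoxon comparison
  clustering.py    z-scoring, 2-partition k-means, composition report
  pipeline.py      end-to-end orchestration with a reproducibility manifest
  cli.py           `radbpe` command-line entry point
  io.py            NIfTI / CSV / JSON I/O
```

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
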