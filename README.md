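# nucleoprog

Quantitative nuclear morphometry for predicting the **time of postoperative
recurrence** in clear cell renal cell carcinoma (ccRCC). After nephrectomy
for localized ccRCC, some patients recur within 5 years, some between 5 and
10, and some never within 10 — and follow-up guidelines give little help
beyond the 5-year mark. This package implements, end to end and on synthetic
data, a prognosis pipeline that reads nuclear shape and chromatin texture
from histology regions of interest (ROIs) and turns them into a predicted
recurrence window. It is aimed at computational-pathology researchers who
want a tested, reusable reference implementation of each stage.

## Pipeline

1. **Per-nucleus features** (`nucleoprog.features`). From a labeled nucleus
   mask plus a grayscale intensity image, each nucleus gets an 80-element
   feature vector: 20 size/shape descriptors, 13 Haralick statistics of the
   within-nucleus gray-level co-occurrence matrix (GLCM) at offset distances
   d ∈ {1, 2, 4, 8} (direction-averaged, symmetric, 8 gray levels), and 8
   radial intensity-distribution statistics over 4 concentric rings.
2. **CFLCM aggregation** (`nucleoprog.cflcm`). The *cell-feature-level
   co-occurrence matrix* lifts Haralick texture from pixels to nuclei: each
   nucleus is treated as one "pixel" carrying a quantized feature value
   (8 equal-frequency levels per ROI), spatial adjacency is a symmetrized
   5-nearest-neighbour graph over centroids, and the co-occurrence matrix
   P(l, l′) of neighbouring level pairs measures spatial heterogeneity.
   Per base feature the ROI keeps 12 statistics — mean, SD, and 10 CFLCM
   statistics (contrast, dissimilarity, homogeneity, angular second moment,
   entropy, correlation, cluster shade, cluster prominence, maximum
   probability, inverse difference moment) — giving a 960-element ROI vector.
3. **Dual-horizon prognosis** (`nucleoprog.prognosis`). Cases are grouped by
   outcome (A: recurrence ≤ 5 y; B: recurrence in 5–10 y; C: censored at
   5–10 y; D: recurrence-free > 10 y), split 3:1 by case, and two
   linear-kernel SVMs with Platt probability calibration are trained on
   z-scored ROI vectors: a 5-year model (A vs B/C/D) and a 10-year model
   (A/B vs D; C is prediction-only). A case's probability is the mean of its
   ROI probabilities, with p > 0.50 called recurrence. The pair (p5, p10)
   maps to a quadrant of the unit square = a predicted recurrence window:
   Q1 → within 5 y, Q2 → 5–10 y, Q3 → recurrence-free within 10 y, Q4 →
   contradictory.
4. **Evaluation** (`nucleoprog.evaluation`) and **synthetic data**
   (`nucleoprog.simulate`): confusion matrices/accuracies at ROI and case
   level, result bundles, and seeded generators for both rendered ROI images
   (textured elliptical nuclei) and cohort-scale per-nucleus feature tables.

## Worked example

```python
from nucleoprog import DualHorizonModel
from nucleoprog.simulate import CohortSpec, generate_cohort, attach_roi_vectors

spec = CohortSpec(
    n_cases_per_group={"A": 8, "B": 6, "C": 6, "D": 6},
    rois_per_case=4, nuclei_per_roi=60, seed=0,
)
cases = attach_roi_vectors(generate_cohort(spec))   # 26 cases, ROI vectors (4, 960)
results = DualHorizonModel(cases, seed=0).fit()
print(results.summary())
```

prints

```
Dual-horizon recurrence prediction
==================================
cohort: 26 cases (train 21, test 5); seed 0

 10y     test  ROI: accuracy  87.5%  (tp=11 fn=1 fp=1 tn=3)
 10y     test case: accuracy 100.0%  (tp=3 fn=0 fp=0 tn=1)
 10y training  ROI: accuracy 100.0%  (tp=44 fn=0 fp=0 tn=20)
  5y     test  ROI: accuracy  80.0%  (tp=7 fn=1 fp=3 tn=9)
  5y     test case: accuracy  80.0%  (tp=2 fn=0 fp=1 tn=2)
  5y training  ROI: accuracy 100.0%  (tp=24 fn=0 fp=0 tn=60)

group x quadrant (test cases):
quadrant  Q1  Q3
group
A          2   0
B          1   0
C          0   1
D          0   1
```

Reading it: both horizon models separate the held-out ROIs well above
chance, and after averaging ROI probabilities per case the two group-A test
cases land in quadrant Q1 (predicted to recur within 5 years) while the
group-D case lands in Q3 (predicted recurrence-free). With such a tiny
cohort one group-B case is mis-timed into Q1; at the default cohort size
(131 cases, 10 ROIs/case, 100 nuclei/ROI) held-out A/B/D cases land in their
expected quadrants in ≥ 90% of cases.

The same pipeline is scriptable from the shell:

```sh
nucleoprog simulate --spec spec.json --out cohort/
nucleoprog aggregate --features cohort/nucleus_features.csv --out roi.csv
nucleoprog evaluate --roi-features roi.csv --cohort cohort/cohort.csv \
    --seed 0 --out report.json
```

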