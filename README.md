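# wavradiomics

A toolkit for screening hepatocellular carcinoma (HCC) against other focal
liver lesions from multiphase contrast-enhanced CT, built around
wavelet-domain radiomics and sparse logistic feature selection.

Radiomics pipelines for liver lesions face an ill-posed regime: a few
hundred lesions versus thousands of candidate features, most of them
heavily correlated.  This package implements the full workflow for that
setting:

1. **Feature extraction.**  Each lesion ROI, resampled to 1 mm isotropic
   spacing, yields per contrast phase (arterial / venous / delayed)
   100 original-domain features — 18 first-order, 14 mesh-based shape,
   68 texture (GLCM 22, GLRLM 16, GLSZM 16, GLDM 14) — plus 86 features
   (first-order + texture) per subband of an undecimated one-level 3D
   wavelet decomposition (8 subbands, LLL … HHH).  Three phases give
   300 original + 2064 wavelet = **2364 features**.
2. **Sparse logistic selection.**  The selector/classifier is the MAP
   estimate of a logistic likelihood under a Laplacian prior,

   ```
   min_θ  Σᵢ −[yᵢ log σ(θᵀxᵢ + b) + (1−yᵢ) log(1−σ(θᵀxᵢ + b))] + λ‖θ‖₁
   ```

   solved by monotone accelerated proximal gradient (soft-thresholding
   prox, so zeros are exact).  Ridge / elastic-net variants and a linear
   LASSO share the solver.  λ is tuned by Bayesian optimisation
   (GP surrogate, expected improvement) of repeated cross-validated AUC
   over log λ ∈ [10⁻⁶, 10⁶].
3. **Baselines and statistics.**  Variance/correlation filters, PCA
   retention and wrapper top-k selectors; Mann–Whitney AUC, F1, repeated
   stratified CV, bootstrap CIs, DeLong's test and Welch's t-test.
4. **Synthetic phantoms.**  Because clinical cohorts of this kind are
   private, the package ships generators for co-registered 3-phase lesion
   phantoms with class-dependent texture, and for high-dimensional feature
   tables with a known sparse ground truth.

## Worked example

```python
import numpy as np
from wavradiomics.synthetic_data import PhantomSpec, generate_cases
from wavradiomics.radiomics_extract import extract_case, build_feature_table
from wavradiomics.pipeline import LsrPipeline
from wavradiomics.evaluation import repeated_cv_evaluate

spec = PhantomSpec(grid_shape=(24, 24, 16), lesion_semiaxes_mm=(4.5, 4.0, 3.5))
cases = generate_cases(20, 0.5, spec, seed=7)
rows = [extract_case(phases, mask) for phases, mask, _ in cases]
table = build_feature_table(rows, [label for _, _, label in cases])
X = table.drop(columns="label").to_numpy()
y = table["label"].to_numpy()
print(X.shape)

pipe = LsrPipeline(lam_frac=0.05).fit(X, y)
print(pipe.model_.support_size)

report = repeated_cv_evaluate(lambda: LsrPipeline(lam_frac=0.05),
                              X, y, repeats=2, folds=5, seed=0)
print(round(report.metrics["auc"].point, 3))
```

prints

```
(20, 2364)
14
1.0
```

i.e. each phantom yields the full 2364-column multiphase table, the sparse
model keeps 14 of 2364 features on this small cohort, and the repeated-CV
AUC is 1.0 because the default phantom classes are strongly texture- and
enhancement-separated.

A command-line layer wraps the same steps:

```bash
wavradiomics simulate --n-cases 20 --out-dir cohort --seed 7
wavradiomics extract --manifest cohort/manifest.csv --out features.csv --domains both
wavradiomics tune-lambda --features features.csv --out bo_trace.csv
wavradiomics select-eval --features features.csv --selector lsr --classifier lsr
```

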