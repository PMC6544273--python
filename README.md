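# mfsurv

Minkowski-functional texture analysis of grayscale regions of interest, with a
survival-prognosis pipeline built on top. The package targets the kind of
question asked in quantitative neuro-oncology imaging: does the *texture* of
the peritumoral T2-hyperintense region around a glioblastoma — not just its
size — carry information about overall survival beyond standard clinical
covariates (age, extent of resection, MGMT promoter methylation, sex)?

## The method

**Minkowski functionals.** A binary 2D pattern has three Minkowski
functionals: area *A*, perimeter *U*, and the Euler characteristic *χ*
(commonly called *genus* in the MR-texture literature), which equals connected
components minus holes. Treating each foreground pixel as a closed unit
square, the union of squares is a cell complex with *F* faces (pixels), *E*
distinct unit edges and *V* distinct lattice vertices, and

```
A = F
U = -4·F + 2·E          (the number of boundary edges)
χ = F - E + V           (faces - edges + vertices)
```

Under this convention foreground components are 8-connected and holes
4-connected. Both identities are verified in the test suite against
independent oracles: a boundary-edge counter for *U* and a flood-fill
components-minus-holes computation for *χ*.

**Threshold sweep.** The ROI's intensities are normalized (optional division
by a reference-region mean, then min–max rescaling to [0, 1]) and binarized at
11 thresholds `t_k = k/10`; the image at `t = 0` is defined as the whole ROI
and the image at `t = 1` as empty, and binarization keeps pixels *strictly
above* the threshold. The triple (A, U, χ) of each binary image gives a
33-element feature vector per subject (`A0..A10, P0..P10, G0..G10`). A smooth,
homogeneous ROI loses pixels in a few connected chunks as the threshold rises;
a heterogeneous one fragments into many components and holes, which the genus
curve picks up.

**Survival modelling.** Cox proportional-hazards models (Efron tie handling)
are fitted on (i) clinical covariates, (ii) texture features selected by
greedy backward elimination on AIC, and (iii) both combined. Models are
summarized by Harrell's concordance and likelihood-ratio tests on the training
arm and validated on a held-out test arm (event-stratified 7:3 split) with
IPCW prediction-error curves and the integrated Brier score; the covariate-free
Kaplan–Meier of the training arm serves as reference. Sex-stratified
Kaplan–Meier curves with log-rank tests compare survival by MGMT status.

Because patient images cannot be redistributed, the package ships a synthetic
cohort generator (`mfsurv.cohort`): Gaussian-random-field textures inside
deformed elliptical ROIs, with survival times drawn from a proportional-hazards
model whose log-hazard is a known linear function of chosen texture features
and clinical covariates — so every stage is testable against ground truth.

## Worked example

```
$ mfsurv simulate --n 113 --seed 7 --out demo
INFO mfsurv: simulated 113 subjects into demo (censoring 0.18 achieved)

$ mfsurv extract --data demo --out features.csv
INFO mfsurv: wrote 113 x 33 feature table to features.csv

$ mfsurv analyze --features features.csv --clinical demo/clinical.csv --out analysis --seed 1
INFO mfsurv: model clinical  C=0.676  IBS=0.197
INFO mfsurv: model mf        C=0.673  IBS=0.216
INFO mfsurv: model combined  C=0.734  IBS=0.213
INFO mfsurv: reference IBS=0.206
INFO mfsurv: report written to analysis/report.json
```

The simulated cohort links its hazard to age, resection type, MGMT status and
the texture features A1, G2, G5. The log lines show each model's training-arm
concordance (0.5 = chance, 1 = perfect ordering of risks) and its test-arm
integrated Brier score (0 = perfect probabilistic prediction, 0.25 =
uninformative); here the combined clinical + texture model orders patients
best (C = 0.734 vs 0.676 clinical-only). `analysis/report.json` additionally
holds the univariate clinical screen, the AIC-selected feature list, per-model
hazard ratios, the prediction-error curves (also plotted to
`prediction_error.png`) and sex-stratified log-rank tests by MGMT status.

In Python the same pieces are plain functions:

```python
import numpy as np
from mfsurv import minkowski_of_mask, mf_sweep, GrayscaleROI

ring = np.ones((3, 3), int); ring[1, 1] = 0
minkowski_of_mask(ring)          # MinkowskiTriple(area=8, perimeter=16, genus=0)

roi = GrayscaleROI(np.random.default_rng(0).random((32, 32)), np.ones((32, 32), bool))
mf_sweep(roi).flat.shape         # (33,)
```

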