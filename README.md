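# omrad — optimal-margin-region radiomics

`omrad` is a Python toolkit for **margin-band radiomics**: predicting a
binary histopathologic outcome (the motivating case is microvascular
invasion, MVI, in solitary hepatocellular carcinoma) from the MRI
texture of the tissue *around* a lesion, while treating the margin
region itself as a model hyperparameter.

For a lesion mask `M` on an isotropic grid, a margin band is

```
band(a, b) = dilate(M, b) \ erode(M, a)        a, b in 0..10 mm
```

with Euclidean-ball structuring elements — 120 bands plus the original
lesion VOI, 121 regions per lesion. For every region, nine
feature-selection chains (correlation / univariate-logistic / XGBoost /
random-forest / GBM / SVM pre-filters feeding LASSO, with optional
bidirectional-AIC stepwise) build a logistic signature from seven
radiomic features (first-order minimum and GLCM IMC1 on the
log-transformed image, GLCM MCC / NGTDM busyness / GLCM joint entropy on
stationary-wavelet subbands, GLCM cluster shade on the LoG σ=3 mm image,
and lesion shape elongation). The **optimal margin region** and chain
are chosen by ranking internal-test AUC over the 9 × 121 = 1089 models.
The winning signature is dichotomized at the training-cohort Youden
cutoff, and risk groups are compared by Kaplan–Meier/log-rank survival
analysis and chi-square/Fisher association tests.

Because clinical MRI cohorts are rarely shareable, the package ships a
deterministic **phantom-cohort simulator**: hepatobiliary-phase-like
volumes (bright liver, darker ellipsoidal lesion) whose margin-rim
texture heterogeneity is coupled to the label, with label-linked
survival times — so the whole pipeline, including planted-region
recovery, is testable end to end. See `docs/methods.md` for the model
details and the simulator's scope.

## Worked example

Simulate a 240-patient cohort with the heterogeneity effect planted in
the inner 5 mm rim, sweep band pairs with inner 0–6 mm and outer
0–3 mm under two selection chains, and stratify by the training Youden
cutoff (about a minute on one CPU):

```python
from omrad import StudyConfig, run_full_study
from omrad.phantom import PhantomTruth, MarginBandSpec

config = StudyConfig(
    seed=1,
    phantom_n=240,
    phantom=PhantomTruth(planted_band=MarginBandSpec(5, 0), effect_size=2.0, margin_mm=7),
    inner_range=(0, 6), outer_range=(0, 3), include_original=False,
    chains=("lasso+stepwise", "corr+lasso"),
    cv_folds=5,
)
report = run_full_study(config)
sel = report["selected"]
print(sel["region"], sel["chain"], round(sel["auc_internal"], 3))
print("cutoff", round(report["stratification"]["cutoff"], 3),
      "J", round(report["stratification"]["youden_j"], 3))
print("log-rank p (OS, training)",
      round(report["stratification"]["cohorts"]["training"]["logrank_os"]["p"], 5))
```

prints

```
in5_out0 corr+lasso 0.878
cutoff 0.301 J 0.676
log-rank p (OS, training) 0.01341
```

i.e. the sweep recovers the planted inner-5 mm rim (`in5_out0`) as the
optimal margin region with internal-test AUC 0.88; the Youden cutoff
(J = 0.68 on the training cohort) splits patients into risk groups
whose overall survival separates at log-rank p ≈ 0.013. The same
workflow runs from the shell:

```bash
omrad simulate --n 60 --seed 7 --out cohort/
omrad run --cohort cohort/ --seed 7 --out results/
```

writing `report.json`, `auc_matrix.csv` (the full region × chain AUC
table) and `risk_groups.csv`. Reports embed the seed, a config hash and
the package version; re-running the same configuration reproduces them
byte for byte.

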