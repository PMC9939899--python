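# dynrad — dynamic radiomics for multi-phase contrast-enhanced CT

`dynrad` is a Python package for predicting treatment outcomes in
colorectal liver metastases (CRLM) from the way radiomics features
*change* across the vascular phases of a contrast-enhanced CT study,
rather than from any single phase's values. It is aimed at imaging
researchers who have per-phase radiomics feature tables (or NRRD/DICOM
volumes with lesion masks) plus a clinical outcome table, and want a
tested, leakage-aware pipeline from feature construction to evaluated
models.

## The idea

A four-phase abdominal CECT study images the same lesion at the
precontrast (PP), arterial (AP), portal venous (PVP) and delayed (DP)
phases. A static radiomics feature ψ extracted per phase becomes a
short series ψ(x(t₁)), …, ψ(x(t_k)); a dynamic feature is a summary
ϕ of that series. Five transform families are provided:

* **SD** — mean absolute deviation around the across-phase mean f̄:
  `(1/k) Σᵢ |fᵢ − f̄|`
* **DC** — the same deviation relative to the mean: `SD / |f̄|`
* **RCR** — relative change rate per phase pair (j < i):
  `|fⱼ − fᵢ| / |fᵢ|` (6 features per base feature at k = 4)
* **RACR** — pairwise change relative to the mean: `|fⱼ − fᵢ| / |f̄|`
* **P** — least-squares polynomial trend coefficients of fᵢ on the
  phase times

Because contrast kinetics reflect tumour vascularity, these
change-pattern features are natural predictors for antiangiogenic
(bevacizumab) therapy. Downstream, the package evaluates them for two
endpoints:

* **best response** (objective response vs. not, per RECIST 1.1):
  Welch t-test screen → L1-penalised logistic (LASSO) selection →
  LDA / linear SVM / random forest, all under pooled leave-one-out
  cross-validation, with selection refit inside every fold by default
  (an `onepass_selection` switch reproduces the optimistic pre-CV
  variant);
* **progression-free survival**: univariate Cox screen → random
  survival forest risk score (leave-one-out) → median-split
  Kaplan–Meier with log-rank → time-dependent ROC at 90/180/270/360
  days.

A synthetic cohort generator with group-dependent enhancement curves,
mean-matched phase levels and Weibull PFS makes the entire pipeline
runnable and testable without patient data, and exact Fisher /
chi-square baseline-table statistics cover the descriptive side.

## Worked example

```python
from dynrad import (SimulationConfig, simulate_feature_cohort,
                    ResponseModel, PFSModel)
from dynrad.response import build_feature_sets
from dynrad.survival import SurvivalConfig

syn = simulate_feature_cohort(SimulationConfig(
    n_patients=60, n_features=60, n_informative=10,
    effect_size=1.0, pfs_coef=2.0, seed=42))

res = ResponseModel.from_cohort(
    syn, feature_sets=("RCR", "SD", "AP", "PP"),
    classifiers=("LDA", "SVM"), seed=42).fit()
print(res.summary())

feats = build_feature_sets(syn.phases, ["RCR"])["RCR"]
pfs = PFSModel(feats, syn.cohort,
               config=SurvivalConfig(n_trees=100, seed=42)).fit()
print(pfs.summary())
```

prints

```
===============================================
Leave-one-out AUC by feature set and classifier
===============================================
      LDA   SVM
RCR 1.000 1.000
SD  0.887 0.920
AP  0.255 0.275
PP  0.457 0.419
===============================================
...
Best cell: RCR / LDA (AUC 1.000, accuracy 1.000)
Selection: nested (refit per fold)

PFS risk score (random survival forest, leave-one-out scores)
  screened features (72): feat_0000__RCR_1to2, feat_0000__RCR_1to3, ...
  median split: 30 high-risk vs 30 low-risk
  log-rank chi2 = 49.422, p = 2.06e-12
  Harrell's C = 0.799
  time-dependent ROC: AUC(90d)=0.920, AUC(180d)=0.935, AUC(270d)=0.931, AUC(360d)=0.969
```

Reading it: the generator plants the response signal in the
phase-to-phase *ratios* of 10 informative features while matching the
phase-averaged levels between groups, so the RCR set separates the
groups perfectly under LOOCV while the single-phase static sets (AP,
PP) hover at chance — the qualitative advantage of dynamic over static
features, by construction. The same RCR features drive the simulated
hazard, so the forest risk score splits the cohort into clearly
different PFS groups (log-rank p ≈ 2e-12) and discriminates events at
every horizon.

A command-line interface mirrors the library
(`dynrad simulate | extract | dynamics | select | evaluate | survival | table2 | run`);
`dynrad run config.json --out results/` executes the whole pipeline
from a declarative JSON config and writes feature tables, evaluation
grids, survival JSON and a decision log.

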