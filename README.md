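# atlasfusion

Multi-modal, multi-atlas classification of mild cognitive impairment (MCI)
from MRI-derived features: voxel-wise **Hurst exponents** (long-range
temporal dependence of the resting-state BOLD signal, estimated by rescaled
range) and regional **gray-matter volumes** (from modulated GM probability
maps), extracted under interchangeable brain parcellations, selected by
**MRMR + sequential feature collection**, and classified by an RBF-SVM under
**nested leave-one-out cross-validation** — with single/multi-modality ×
single/multi-atlas integration strategies including majority-vote bagging.

It is aimed at neuroimaging researchers who have spatially preprocessed
fMRI/sMRI data and want a leak-free, auditable implementation of this
feature-extraction → selection → classification design, plus synthetic
generators to validate every stage.

## The method in brief

For a voxel series cut into blocks of length *n*, the rescaled range is
R/S = (max − min of the mean-adjusted cumulative sum) / (block SD); the
Hurst exponent *h* is the slope of log⟨R/S⟩ against log *n* (h = 0.5
memoryless, h > 0.5 persistent). Features f are ranked greedily by

&nbsp;&nbsp;&nbsp;&nbsp;max over f of [ I(f, C) − (1/|S|) Σ over s in S of I(f, s) ]

(mutual information relevance minus mean redundancy against the selected set
S), and every contiguous window of the top-50 ranking is scored by
inner-LOOCV SVM accuracy (C, γ grid-searched over 2^−8 … 2^8) to pick the
optimal subset. All selection and tuning run strictly inside each outer
LOOCV fold.

## Worked example

`examples/` holds one short script per capability. For instance,

```bash
python examples/nested_classification.py
```

prints (numbers computed at run time):

```
planted effect (d = 2.5, 3 informative of 12 features, n = 30):
  accuracy 0.967  sensitivity 1.000  specificity 0.933  AUC 0.969
  per-fold selected-window sizes, mode: 2

same table, labels permuted:
  accuracy 0.433  AUC 0.347
```

The planted group difference is recovered almost perfectly, while the same
pipeline on permuted labels collapses to chance — the signature of selection
and tuning running only on each fold's training subjects. The other examples
cover Hurst estimation on exact fractional Gaussian noise
(`hurst_estimation.py`), image-space feature extraction on a simulated
cohort (`extract_features.py`), the MRMR + SFC search
(`feature_selection.py`), and the four integration strategies
(`multiatlas_strategies.py`).

From Python, the core loop is three calls:

```python
from atlasfusion import (CohortSpec, ClassifierConfig, SelectionConfig,
                         nested_loocv, simulate_feature_table)

table = simulate_feature_table(
    CohortSpec(n_positive=20, n_negative=20, effect_size=3.0, seed=11),
    n_features=16, n_informative=3)
result = nested_loocv(table, ClassifierConfig(), SelectionConfig(mrmr_k=16))
print(result.metrics.as_dict())
```

## Command line

A thin CLI wraps the library for shell pipelines:

```bash
atlasfusion simulate    --out-dir cohort --seed 1 --n-pos 6 --n-neg 6
atlasfusion extract-he  --data-dir cohort --tr 2.0 --drop-initial 0 --out he.csv
atlasfusion extract-gmv --data-dir cohort --out gmv.csv
atlasfusion run         --manifest manifest.yaml   # metrics.csv + audit JSONs
```

The YAML manifest names the per-(modality, atlas) feature CSVs, the
hyperparameter grids, and the strategies to run; every audit JSON carries a
provenance block (config hash, seed, version). Real data enters the same
way: NIfTI label images via `load_atlas` (with exclusion lists), 4D NIfTI +
confound TSVs via `extract-he`, modulated GM maps via `extract-gmv`.

## Layout

```
src/atlasfusion/   atlas, timeseries, hurst, morphometry, selection,
                   classify, integrate, synthetic, cli
tests/             unit + property tests and end-to-end acceptance checks
examples/          one narrative script per capability
docs/methods.md    models, parameter choices, limitations
```
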