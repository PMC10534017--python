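# mfcrad

Multi-feature-combined (MFC) radiomics for predicting **local failure** —
tumor recurrence at the treated site — after surgery or stereotactic body
radiotherapy (SBRT) in early-stage non-small-cell lung cancer, from
pre-treatment CT.

The package is for imaging/outcomes researchers who want a complete,
inspectable implementation of this class of pipeline: per patient it
extracts **105 handcrafted radiomic features** of the gross tumor volume
(13 shape, 18 intensity, 20 histogram, 22 GLCM, 16 GLRLM, 16 GLSZM; IBSI
conventions, fixed-bin-number discretization with 32 bins), **512 deep
features** from a frozen five-block 3D convolutional encoder with global
average pooling applied to an 8×8×8 cm³ volume of interest, and the
**clinical covariates** (gender, age, tumor volume, Charlson comorbidity
index, plus dose and fractionation for SBRT). Four model variants are
compared — PI (clinical only), R (handcrafted only), DL (encoder + sigmoid
head), MFC (everything) — under three classifier backends (L2 logistic
regression, RBF-SVM, random forest), evaluated by leave-one-out
cross-validation and 100-fold Monte-Carlo random validation (stratified
70/30 splits), with AUC as the pairwise concordance probability and paired
t-tests between models.

Because no clinical images are distributed, the package ships a synthetic
phantom cohort generator that reproduces the study conditions (83 subjects
with 7 events for the surgery-like cohort; 84 with 9 for SBRT-like; tumors
0.6–6 cc in lung-like −800 HU background) with a configurable planted
image–outcome effect, so the whole pipeline is testable end-to-end.
See `docs/methods.md` for the model, conventions and limitations.

## Worked example

Generate a surgery-like phantom cohort with a planted +60 HU intensity
shift and ×1.5 heterogeneity in event-positive tumors, featurize it, and
compare the variants with 20-fold Monte-Carlo validation:

```python
import numpy as np, pandas as pd
from mfcrad import surgery_preset, generate_cohort, build_dataset
from mfcrad.models import ModelVariant, ClassifierSpec, HeadSpec
from mfcrad.fusion import FusionConfig
from mfcrad.validation import run_mcrv

cfg = surgery_preset(seed=0, effect_mean_hu=60.0, effect_texture=1.5)
cases, manifest = generate_cohort(cfg)          # 83 phantoms, 7 events
ds = build_dataset(cases, encoder_seed=0)       # 105 + 512 + 4 = 621 columns

for name in ("PI", "R", "MFC", "DL"):
    variant = ModelVariant(name=name,
                           classifier=ClassifierSpec(kind="logistic", seed=0),
                           head=HeadSpec(seed=0), fusion=FusionConfig(seed=0))
    res = run_mcrv(ds.table, ds.labels, variant, n_folds=20, seed=0)
    print(f"{name}: mean AUC {res.folds['auc'].mean():.3f} "
          f"± {res.folds['auc'].std():.3f}")
```

Output (about 7 minutes on one CPU, most of it feature extraction):

```
PI: mean AUC 0.749 ± 0.175
R: mean AUC 1.000 ± 0.000
MFC: mean AUC 0.999 ± 0.005
DL: mean AUC 0.823 ± 0.166
```

Reading: the planted 60 HU shift makes the tumors' mean intensity almost
perfectly separating, so the handcrafted-radiomics model (R) saturates at
AUC 1.0 and the all-blocks MFC model sits at the same ceiling. The deep
variant (DL) detects the shift through a *random-weight* encoder — a fixed
nonlinear projection — but less cleanly than the explicit intensity
features; with pre-trained weights loaded it would be stronger. The
clinical-only model (PI) has no planted signal; its above-chance mean here
is in-cohort chance association of demographics with only 7 events (with
permuted labels every variant falls to 0.47–0.60). `res.summary()` formats
each variant's AUC/sensitivity/specificity/accuracy as `mean ± SD`, and
`mfcrad.report.render_report` writes the variant × classifier table, the
paired t-test p-value grid and the mean-ROC figure with ±1 SD bands.

The same pipeline is scriptable from the shell:

```bash
mfcrad synth --preset surgery --effect-hu 60 --effect-tex 1.5 --seed 0 --out cohort/
mfcrad radiomics --manifest cohort/manifest.csv --out handcrafted.csv
mfcrad deepfeat  --manifest cohort/manifest.csv --random-seed 0 --out deep.csv
mfcrad fuse --handcrafted handcrafted.csv --deep deep.csv \
            --manifest cohort/manifest.csv --out fused.csv
mfcrad evaluate --fused fused.csv --manifest cohort/manifest.csv \
                --scheme mcrv --folds 20 --seed 0 --out results/
# or everything at once from a YAML config:
mfcrad all --config run.yaml
```

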