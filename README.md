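# tsr-slide

Automated estimation of the **tumor–stroma ratio (TSR)** from
hematoxylin–eosin (H&E) stained whole-slide images of colorectal cancer.

The proportion of stroma at the tumor site is a prognostic factor in many
solid tumors: stroma-high cases (TSR > 50%) carry a worse prognosis than
stroma-low cases (TSR ≤ 50%). Pathologists score TSR visually on a coarse
grid {10%, 20%, …, 90%}, with limited inter-observer reproducibility. This
package implements the patch-based pipeline for scoring TSR computationally:

1. **Tissue masking** — a binary mask built with Otsu's threshold on the
   saturation channel removes image background and adipose tissue.
2. **Tiling** — slides are cut into 224 × 224 px windows. Training tiling
   slides a window with 64 px overlap over annotated slides and keeps windows
   with ≥ 75% annotated pixels (labeled by majority class); inference tiling
   uses a non-overlapping grid and keeps windows with ≥ 75% masked tissue.
3. **Stain normalization** — Macenko's method, implemented from the optical
   density (OD) transform up: `OD = −log10(I/I₀) = S·c`, stain vectors
   estimated from the leading plane of the OD point cloud via angle
   percentiles, concentrations re-rendered through a reference stain model.
4. **Patch classification** — a 3-class softmax classifier
   (*tumor*/*stroma*/*other*) with a pluggable backbone (default: a compact
   numpy CNN) and three transfer-learning setups: pretrained-init →
   domain pre-training → fine-tuning (SETUP-1), pretrained-init →
   fine-tuning (SETUP-2), random-init → domain pre-training → fine-tuning
   (SETUP-3). Hyperparameters by 5-fold cross-validation, epoch budget by
   early stopping on ⅓ of the training patches, final retrain on all of it.
5. **TSR** — per slide,

   ```
   TSR = n_stroma / (n_tumor + n_stroma)
   ```

   over the classified patches (*other* counts toward neither side), then
   dichotomized at the 50% cutoff.
6. **Evaluation** — confusion matrix, accuracy, per-class
   precision/recall/F1; and against visual TSR scores: per-category
   mean/median/std/SEE, Pearson *r*, overall SEE (the RMS deviation from the
   assigned category value), and Cohen's κ of the stroma-high/low calls.

A first-class synthetic-slide generator renders H&E-like slides by
Beer–Lambert stain mixing (`I = I₀·10^(−S·c)`) over known layouts, with
exact label maps, region areas and expected patch-count TSR — so the entire
pipeline is testable end to end without clinical data.

## Worked example

```python
import numpy as np
from tsr_slide import (
    DEFAULT_REFERENCE, TrainConfig, estimate_slide_tsr,
    make_patch_dataset, run_setup,
)
from tsr_slide.pipeline import normalize_patchset
from tsr_slide.synth import make_tsr_cohort

# train a classifier on stain-normalized synthetic patches (SETUP-2)
train = normalize_patchset(make_patch_dataset(600, seed=101), DEFAULT_REFERENCE)
model = run_setup("SETUP2", None, train,
                  TrainConfig(setup="SETUP2", max_epochs=12, patience=3, seed=7))

test = normalize_patchset(make_patch_dataset(100, seed=202), DEFAULT_REFERENCE)
print(f"held-out patch accuracy: {model.accuracy(test):.3f}")

# score a 30-slide synthetic cohort with known ground truth
preds, trues = [], []
for slide, truth in make_tsr_cohort(n_slides=30, seed=0):
    result = estimate_slide_tsr(slide, model)
    preds.append(result.tsr); trues.append(truth.expected_tsr)
preds, trues = np.array(preds), np.array(trues)
print(f"cohort r = {np.corrcoef(preds, trues)[0, 1]:.3f}, "
      f"MAE = {100 * np.abs(preds - trues).mean():.1f} pp")
```

prints (exactly, single-threaded):

```
held-out patch accuracy: 0.997
cohort r = 0.983, MAE = 6.5 pp
```

i.e. the trained classifier recognizes 99.7% of held-out pure-class patches,
and the slide-level TSR estimate tracks the ground-truth patch-count TSR
across the cohort with a mean absolute error of about six TSR points.

The same stages are scriptable from the shell:

```bash
tsr-slide synth slide --seed 3 --size 1568 --out slides/
tsr-slide mask  --in slides/synth-3.png --out mask.png
tsr-slide tile  --mode infer --slide slides/synth-3.png --mask mask.png --out tiles/
tsr-slide score --model model --slides slides/ --out tsr.csv
```

## Layout

| module | contents |
|---|---|
| `tsr_slide.synth` | synthetic slides, patch sets, domain pairs, TSR cohorts |
| `tsr_slide.stain` | OD transform, Macenko estimation, normalization |
| `tsr_slide.mask` | histogram Otsu, tissue-mask construction |
| `tsr_slide.tiling` | window enumeration, training/inference tiling |
| `tsr_slide.nn`, `tsr_slide.classifier` | numpy CNN backbone, setups, CV, early stopping |
| `tsr_slide.tsr` | the TSR statistic, dichotomization, slide scoring |
| `tsr_slide.metrics` | classification report, Pearson r, SEE, Cohen's κ, TSR tables |
| `tsr_slide.pipeline`, `tsr_slide.cli` | workflows, YAML config, `tsr-slide` CLI |

See `docs/methods.md` for the model details, parameter choices and known
limitations.
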