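# her2mil

Weakly supervised scoring of HER2 immunohistochemistry (IHC) from
tissue-microarray (TMA) spot images.

HER2 status decides whether a breast-cancer patient is eligible for
anti-HER2 therapy. Pathologists grade the brown DAB staining of a spot with
an IHC score 0–3: scores 0/1 are HER2-negative, 3 is positive, and the
equivocal score 2 has to be resolved with an in-situ hybridisation (ISH)
assay (positive when HER2/CEN17 ≥ 2.0 or mean HER2 signals ≥ 6.0). This
package implements, at desk scale and fully offline, a pipeline that learns
those calls directly from the stained image:

* **Attention-based multiple-instance learning (MIL).** A spot is a *bag*
  of non-overlapping square tiles. Each tile is embedded by a convolutional
  encoder, h_k ∈ R^d; an attention network scores every embedding

      a_k = exp(wᵀ tanh(V h_k)) / Σ_j exp(wᵀ tanh(V h_j)),

  and the bag representation z = Σ_k a_k h_k (invariant to bag size and
  tile order) feeds a feed-forward classifier for the IHC score (4-class)
  or HER2 status (binary). The attention weights, mapped back to the tile
  grid, show *where* the model looked.
* **Stain mathematics.** Beer–Lambert optical density, H-DAB colour
  deconvolution (Ruifrok–Johnston vectors), Macenko stain estimation and
  cross-cohort stain matching (deconvolve → rescale concentrations →
  reconvolve).
* **Staining-intensity baseline.** The comparator without morphology: each
  spot is summarised by d_max, the maximum over tiles of the mean DAB
  concentration, classified by logistic regression.
* **Evaluation.** Confusion matrices (predicted × true), balanced accuracy
  (macro-averaged recall), support-weighted precision/recall/F1 and
  one-vs-all ROC/AUC — the exact conventions needed to reproduce published
  reference tabulations.
* **Synthetic TMA generator.** Labelled circular spots with
  hematoxylin-toned nuclei and membranous DAB rings whose intensity and
  completeness follow the IHC score, including a `morphology_only` regime
  where the equivocal statuses share one intensity distribution and differ
  *only* in membrane pattern — so the MIL-vs-baseline contrast can be
  demonstrated without any real data.

Everything (including the neural networks, trained with Adam and
reduce-on-plateau scheduling) runs in float64 numpy on one CPU.

## Worked example

```python
import numpy as np
from her2mil import (generate_cohort, tile_image, AttentionMILClassifier,
                     IntensityBaselineClassifier, slide_descriptor,
                     balanced_accuracy, confusion)
from her2mil.training import stratified_split

cohort = generate_cohort(200, (0, 0, 1, 0), regime="morphology_only",
                         seed=0, side_px=192, tile_size=32)
bags = [tile_image(im, tile_size=32, discard_empty=True)
        for im in cohort.images]
y = np.array([lab.her2_status for lab in cohort.labels])

plan = stratified_split(cohort.labels, seed=0)
ids = [lab.spot_id for lab in cohort.labels]
val = np.array([ids.index(s) for s in plan.val_ids])

mil = AttentionMILClassifier(tile_size=32, random_state=0).fit(
    bags, y, val_indices=val)
base = IntensityBaselineClassifier().fit(
    [slide_descriptor(bags[i]).d_max for i in np.setdiff1d(range(200), val)],
    y[np.setdiff1d(range(200), val)])

for name, pred in [("MIL", mil.predict([bags[i] for i in val])),
                   ("intensity baseline",
                    base.predict([slide_descriptor(bags[i]).d_max for i in val]))]:
    print(name, balanced_accuracy(confusion(y[val], pred, [0, 1])))
```

prints (about four minutes of CPU training):

```
MIL 1.0
intensity baseline 0.35
```

These 200 score-2 spots carry their HER2 status purely in the membranous
staining *pattern*: the intensity-only baseline has no real signal to use
(its held-out score is chance-level noise — here below 0.5, having fitted
sampling noise with the wrong sign) while the MIL classifier resolves the
status from morphology. On an `intensity_coded`
cohort both models instead reach ≥ 0.9 balanced accuracy.

A thin CLI mirrors the library (`her2mil synth / tile / stain-normalize /
train / predict / heatmap / baseline / evaluate`).

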