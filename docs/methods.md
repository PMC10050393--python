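# Methods

## Problem setting

A tissue-microarray spot is one square RGB image of a HER2-stained breast
tumour core. The clinical ground truth is hierarchical: an IHC score in
{0, 1, 2, 3}, and a binary HER2 status that is determined by the score
except for the equivocal score 2, where an ISH assay decides (positive iff
HER2/CEN17 ≥ 2.0 or mean HER2 signals ≥ 6.0 over 20 tumour cells; the
package implements both boundaries as inclusive, and the label container
refuses a status that contradicts the score/ISH-derived one).

Supervision is weak: labels attach to whole spots, never to tiles. The
package therefore treats a spot as a bag of tiles and learns bag-level
classifiers.

## Models

### Attention-MIL classifier

Tiles are non-overlapping squares cut row-major from the top-left
`floor(side/tile)` grid; right/bottom remainders are dropped rather than
padded so every tile is exactly the configured size. A tile is discarded
as "empty" when fewer than 10% of its pixels exceed a summed optical
density of 0.15 (the same transparency cut Macenko estimation uses); both
numbers are configuration keys. All-black tiles are kept but logged —
scanner artefacts should reach quality control, not silently vanish.

Each tile is encoded to h_k ∈ R^d, attention weights are
a_k = softmax_k(wᵀ tanh(V h_k)) with a max-subtracted softmax, the bag
vector is z = Σ a_k h_k, and a dense head maps z to class logits. The
un-gated attention operator is the default; V is L×d with L = 128 by
default. Because the weights lie on the simplex, the bag representation is
invariant to tile order and (with renormalisation) to tile duplication;
both invariances are asserted by tests, and the whole backward pass is
checked against central finite differences at 1e-4 relative tolerance.

Two encoder regimes exist: `"conv"` (a 3-block conv/ReLU/max-pool trunk
with global average pooling and a dense projection, trained end-to-end
with the bag loss) and `"identity"` for precomputed/frozen embeddings.
End-to-end is the default; whether to freeze a pretrained trunk is left as
a mode switch because either choice is defensible under weak labels.

Scale presets: the full-scale configuration of record uses 224 px tiles,
d = 512 (a ResNet34-class trunk) and the published optimisation settings
(Adam, weight decay 1e-8, betas 0.9/0.999; MIL learning rate 5e-9 with
reduce-on-plateau factor 0.3 / patience 40; whole-image learning rate 1e-5
with factor 0.1 / patience 20; batch sizes 1 and 32). The desk preset —
the default here — uses 32 px tiles, d = 64, L = 128, learning rate 1e-4,
factor 0.3, patience 8, and stops after two plateau reductions, so a
200-spot synthetic cohort trains in about three minutes on one CPU. All
presets are plain configuration values with no hidden overrides.

Training uses unweighted cross-entropy with class balance handled by the
sampler (inverse-class-frequency weighted sampling with replacement), and
random horizontal/vertical flips (each with probability 0.5) as
augmentation. One master seed fans out to the split, sampler, augmentation
and initialisation streams. The checkpoint kept is the one with the best
validation balanced accuracy; the plateau scheduler monitors the same
quantity — balanced rather than raw accuracy, so model selection stays
consistent with how performance is reported under class imbalance.

### Whole-image classifier

The resolution-robustness comparator: downscale the spot (area-averaging
by default, bilinear opt-in) to a fixed side and classify in one shot with
a residual CNN. The desk preset is a 4-block channel-preserving residual
net on 64 px inputs; the full-scale preset mirrors a ResNet34 on 1024 px
inputs (5468/1024 ≈ 5.34).

### Staining-intensity baseline

Colour-deconvolve the spot, average the DAB concentration per tile, take
the maximum over tiles (d_max), and fit a logistic regression (multinomial
for score, binary for status) on that single feature — max-aggregated MIL
with one hand-crafted feature. The descriptor deliberately uses OD-scale
DAB *concentration*, not raw luminance: "the staining channel" after
deconvolution is the DAB plane. A small L2 penalty (1e-3) keeps the 1-D
fit conditioned. Any signal carried by staining pattern rather than
staining amount is invisible to this model by construction.

## Stain mathematics

Optical density is od = −log10(max(I, 1)/I₀) per channel (base-10
throughout, the Ruifrok convention; a natural-log toggle exists).
Deconvolution solves c·M = od per pixel for the 3×3 stain matrix M whose
rows are unit OD vectors (hematoxylin, DAB, residual); negative
concentrations are retained, and least squares replaces the direct solve
above condition number 1e8. The fixed default profile is the published
Ruifrok–Johnston H-DAB pair with the unit cross product as residual.

Macenko estimation removes pixels with summed OD below β = 0.15, takes the
two principal directions of the remaining OD cloud, and returns the
α = 1st/99th percentile extreme-angle directions as stain vectors with
99th-percentile robust concentrations (α, β are the original method's
values). The row with the *smaller* blue-channel OD is labelled
hematoxylin: a blue stain transmits blue light, so its blue absorbance is
the low one (the Ruifrok H-DAB vectors have blue OD 0.286 vs 0.776).
Rank-deficient clouds — including the near-collinear extremes an 8-bit
single-stain image produces — raise an error advising the fixed fallback
profile. Stain matching deconvolves with the source profile, rescales the
two stain concentrations by the ratio of robust maxima, reconvolves with
the target matrix and clips to 8 bits; white is a fixed point. Both
per-image and one-profile-per-cohort normalisation modes are exposed, as
which one a given cohort needs is a data question.

## Interpretability

Attention and per-tile mean-DAB heatmaps are min–max normalised to [0, 1]
per spot (per-spot, because the reference visualisations are single-spot
panels); a degenerate zero range yields an all-zero map with an explicit
`constant` flag rather than NaN. Discarded tiles are rendered as NaN
sentinels so blanks are never confused with low attention. The
discordance mask |attention − intensity| > δ turns "the model attends
where the stain is not" from a visual impression into a computable
artefact. Tile embeddings are projected with scikit-learn's t-SNE
(perplexity 30 capped below the point count, seeded) — plumbing, not a
re-implementation.

## Evaluation conventions

Confusion matrices are oriented predicted × true. Balanced accuracy is
the *unweighted* macro-average of per-class recalls, while precision,
recall and F1 are *support-weighted* (weights = true-class counts / n).
This mixed reading is deliberate: it is the only convention under which
the published status-row metrics (0.9429 / 0.9705 / 0.9478 / 0.9551) are
all reproduced from the published cross-tabulation, and the reproduction
is asserted to 2×10⁻⁴ — the reference values appear to be truncated, not
rounded, at four decimals. Support-weighted recall algebraically equals
overall accuracy; that identity is property-tested. ROC curves are
one-vs-all per class with trapezoid AUC and tie grouping; a class absent
from the truth yields an explicitly missing AUC.

## Synthetic data generator

Each spot is a circular disc (radius 0.45·side ± 3%) on white, with
Poisson-placed nuclei (density 3 cells per tile area of tissue) rendered
as hematoxylin Gaussian blobs over a low-frequency stromal texture. DAB is
rendered in two components:

* membranous rings (annuli at 1.6× nucleus radius) whose peak OD, arc
  completeness and stained-cell fraction increase with IHC score
  (0: 0.02/0.10/0.05 → 3: 1.15/0.95/0.95);
* a diffuse "confluent sheet" floor in one hotspot region, composited
  with `max` so the rendered DAB OD never exceeds the nominal peak — this
  is what makes d_max recover the configured peak OD through
  deconvolution.

The composite passes through Beer–Lambert with the fixed H-DAB profile,
plus per-channel Gaussian OD noise (sd 0.02) and mild quadratic vignetting
(0.04 OD at the corners) so stain estimation is exercised non-trivially.

Regimes: in `intensity_coded`, equivocal-positive spots are rendered with
higher peak DAB than equivocal-negative (0.90 vs 0.55), so intensity alone
resolves status. In `morphology_only`, both statuses share one peak-OD
distribution (0.72) and the per-cell DAB mass is equalised by
construction: incomplete membranes are drawn as non-overlapping arc
fragments (one per equal sector) whose *thickness* scales inversely with
completeness at identical OD, so arc length × thickness — the covered
area — is constant. Keeping the OD identical also keeps 8-bit
quantisation bias identical across morphologies; equalising through
darker fragments instead measurably leaked intensity signal. A two-sample
test on d_max between the statuses is non-significant at n = 100, and the
baseline's d_max AUC sits at chance level across seeds.

Score-2 spots receive simulated ISH counts drawn from supports that
reproduce the intended status under the reading rule with probability one
(positive: ratio U[2.2, 8] or signals U[6.5, 12]; negative: ratio
U[0.8, 1.8] with CEN17 ≤ 3, hence signals < 6).

Cohort score proportions default to the one fully printed reference
distribution (416/186/14/37 of 653, apportioned by largest remainder);
the desk-scale pipeline experiments instead use a balanced quarter mix
(and, for `morphology_only`, an all-score-2 cohort split evenly by
status), chosen once so every stratum is populated usefully at n ≈ 200.
Default spot geometry is 1344 px with 224 px tiles; the pipeline
experiments use 192 px spots with 32 px tiles — the desk preset's
geometry — so a full generate-train-evaluate cycle stays within minutes.

What the generator does *not* emulate: real nuclear pleomorphism and
chromatin texture, stromal/tumour architecture, cytoplasmic vs membranous
ambiguity, scanner optics, or staining-batch variation beyond a global
profile shift. Passing the desk-scale comparison therefore shows that the
pipeline recovers the *kind* of signal each model can use (intensity vs
membranous pattern), not that it attains any particular accuracy on real
cohorts.

## Splits and sampling

Train/validation splitting is stratified per IHC score with score-2 spots
further stratified by HER2 status; each stratum contributes
floor(0.8·n) spots to training and the remainder to validation (a
round-to-nearest flag exists; the floor rule is the default because the
reference train/validation counts are consistent with floor-dominant
rounding but not uniquely determined by them). A single-spot stratum goes
to validation with a warning. Inverse-frequency sampling weights make the
expected class frequency uniform under sampling with replacement; the
empirical frequency over 10,000 draws is tested to within three standard
errors.

## Numerical choices and limitations

float64 everywhere; softmax with max subtraction; intensities clipped to
≥ 1 before logs; non-finite losses abort with the failing stage named.
The numpy networks are small by design — convolutions via im2col, 2×2 max
pooling with tied-gradient sharing — and are validated by
finite-difference checks rather than scale. Known limitations: no GPU
path, no whole-slide pyramid formats, no multi-head/gated attention (the
gated variant is a flag on the roadmap, not implemented), and the CLAM
family of instance-clustering losses is intentionally out of scope. The
published full-cohort accuracies require the original data and
GPU-scale training; nothing in this package claims to reproduce them
beyond the metric arithmetic and the direction of the MIL-vs-intensity
gap.
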