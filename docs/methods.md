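# Methods

## The model

`idfnet` implements an interpretable dynamic fusion classifier for
trimodal imaging of colorectal lesions: an endoscopy-like RGB frame, a
CT-like slice on the Hounsfield-unit scale, and a histology-like RGB patch
per case, with a binary benign/malignant label. The pipeline is

1. **Modality encoders.** Each modality has its own backbone mapping images
   to a shared `d_latent` space. CT slices are encoded per slice and
   aggregated by global average pooling; histology patches are encoded per
   patch and aggregated by learned attention pooling (multiple-instance
   style). The default backbones are a three-block strided CNN and a
   two-layer patch transformer, small enough to train from scratch on one
   CPU core in under a minute; the configuration enum also declares
   large-scale backbones (`resnet50`, `efficientnet_b3`, `vit_base`) behind
   the same interface, which require externally supplied weights.
2. **Stage 1 — reliability gating.** A per-modality sigmoid gate
   `g_m = σ(w_m·f_m + b_m)` produces a scalar per case that attenuates the
   embedding: `f̃_m = g_m · f_m`.
3. **Stage 2 — entropy-regularized routing.** Softmax routing weights
   `g_i = softmax_i(W_i·f̃_i + b_i)` are computed from the gated embeddings.
   The routing inputs are soft-length-normalized (`v/√(1+‖v‖²)`) so a
   degenerate embedding (for instance from a zeroed input) cannot produce an
   extreme logit and hijack the softmax.
4. **Cross-modal attention fusion.** The three routed tokens — embeddings
   unit-normalized per case, then scaled by `g_i·g_m` — form a 3-token
   sequence processed by bidirectional multi-head attention; the attended
   tokens are **summed** and projected through one weight-shared linear map
   to `d_fused`.
5. **Classifier.** `d_fused → d_fused/4 → 1` with ReLU, dropout 0.3
   (training only) and a sigmoid malignancy probability.

The composite loss is `L_total = L_BCE + λ·L_ent + β·L_L2` with λ = 0.01
and β = 0.001 by default. `L_ent` is the **negative** mean routing entropy,
i.e. an entropy bonus: minimizing the total maximizes entropy, which is the
only sign consistent with the regularizer's purpose of preventing modality
collapse (the literal `+H` penalty, which rewards confident routing, is
available as `entropy_sign="literal"` for comparison). λ is applied exactly
once. `L_L2` is the mean squared encoder/fusion weight — normalizing by
parameter count keeps β = 0.001 "mild" at any model width (a raw sum
dominates the loss as the model grows) — and the classifier head is
excluded by default (`l2_include_head` flips this).

### Why the fusion stage is normalized and weight-shared

Two design choices in step 4 depart from the obvious
"concatenate-and-project" construction, and both exist to keep the routing
weights *identifiable* — i.e. to make the reported `g_i` actually mean
"this modality's contribution":

* If attended tokens are concatenated and passed through a slot-specific
  projection, the projection can renormalize or null any token, so the
  routing weights become a gauge freedom: in development runs, trained
  models assigned more than 80 % routing weight to a pure-noise modality
  while classifying perfectly through downstream compensation. Summing the
  attended tokens and projecting through a single shared map removes the
  per-slot degrees of freedom: the gate/routing scaling is then the only
  channel that sets a modality's contribution.
* Unit-normalizing the token content makes every modality offer content of
  identical magnitude, so raw embedding norms cannot substitute for gates.

With these, training with one planted zero-reliability modality drives that
modality's mean routing weight to the bottom of the three consistently
across seeds — the headline mechanism check.

### Training protocol

AdamW with a cosine-annealed learning rate, early stopping on validation
AUC, everything seeded. Two presets:

| parameter | desk | paper-scale |
|---|---|---|
| d_latent / d_fused / heads | 32 / 64 / 4 | 1024 / 2048 / 8 |
| image size | 64 px | 128+ px |
| lr → min lr | 2e-3 → 1e-5 | 1e-4 → 1e-6 |
| max epochs / patience | 40 / 12 | 100 / 10 |
| batch size | 16 | 16 |

Weight decay 0.01 and betas (0.9, 0.999) in both presets. Three details
matter at desk scale and are deliberate design choices:

* **Gating warmup.** The gate/routing scaling is blended in linearly over
  the first 6 epochs. Without it, an encoder whose modality starts
  down-routed receives almost no gradient and never learns its cue (a
  bootstrap failure observed as a permanently constant CT embedding).
* **Modality dropout.** Each training input is zeroed per modality with
  probability 0.1 (0.25 in the missing-modality studies), keeping at least
  one modality. This trains the gates on genuinely unreliable inputs and
  makes the zero-tensor missing-modality protocol an in-distribution
  condition; without it, zeroing a modality at evaluation produced
  catastrophic rather than graceful degradation.
* **Encoder weight decay exemption.** Backbone parameters are excluded
  from the optimizer's decoupled weight decay (they are still regularized
  through the explicit `β·L_L2` term). Decaying an encoder that receives no
  task gradient collapses its output to a constant, which hides an
  unreliable input from the gates.
* **Checkpoint tie-breaking.** Among epochs with equal validation AUC the
  later (more converged) checkpoint is kept; the returned model never has
  validation AUC below the best observed.
* **Platt calibration.** Selecting checkpoints on AUC yields rank-accurate
  but under-confident probabilities, so after selection a scalar logistic
  recalibration `p = σ(a·logit + b)` is fitted on the validation split and
  applied at inference. The transform is monotone (`a > 0`), leaving AUC
  and all routing diagnostics untouched while making the Brier score,
  reliability curve and thresholded metrics meaningful.

Early stopping, per-epoch history (loss components, validation AUC and
routing entropy), patient-grouped stratified splits (both a 70/15/15
holdout and 5-fold CV behind one interface), and inverse-frequency
reweighted sampling (enabled automatically beyond a 55/45 imbalance) follow
the standard protocol. The zero-input missing-modality evaluation zeroes
the *raw* image before preprocessing; for CT this yields a constant 0.3
plane after HU windowing, not a zero plane — documented behavior.

## Synthetic data

The generator renders one latent benign/malignant label into three
modality-specific cues: a textured elliptical protrusion on a mucosa-like
background (endoscopy), a locally thickened, contrast-enhancing segment of
a bowel-wall ring phantom on the HU scale [-1000, 1000] (CT), and a region
of elevated nuclear-dot density on an eosin-like background (histology).
Masks mark the planted lesion pixels exactly. Patients own
`cases_per_patient` cases and never straddle the class boundary.

Two knobs control how much signal each modality carries:

* **Reliability** `r ∈ [0, 1]` blends the clean rendering with clipped
  Gaussian noise: `image = r·clean + (1-r)·noise`. The noise mixes iid
  pixels with a smooth low-frequency component (structured acquisition
  artifacts); purely iid noise would average out under global pooling and
  make an unreliable modality indistinguishable from a harmless constant.
  At `r = 0` a modality carries no label information (probe AUC ≈ 0.5).
* **Visibility and miss rate.** Every malignant rendering draws a per-case,
  per-modality lesion contrast from U(0.6, 1.0), and with probability
  `miss_rate` (default 0.12, settable per modality) the lesion is rendered
  nearly invisible in that modality. This emulates the clinical reality
  that no single modality shows every tumour: at the defaults a
  single-modality CNN probe reaches AUC ≈ 0.92–0.97 while the trimodal
  model reaches ≈ 0.99 — the unimodal-vs-multimodal regime the method is
  designed for, and the property that makes leave-one-out degradation and
  gate recovery measurable at all. Per-modality miss rates plant an
  informativeness ordering (the reference studies use
  {endoscopy 0.3, ct 0.3, histology 0.08}, making histology decisively the
  most informative).

What the generator does **not** emulate: photorealistic anatomy, 3-D CT
volumes, whole-slide pyramids, scanner/site batch effects, label noise, or
correlated artifacts across modalities. Passing tests therefore demonstrate
that the mechanisms work as designed on data with known ground truth — not
clinical performance.

## Interpretability

* **Grad-CAM++** per modality from the closed form: with first gradient `G`
  of the pre-sigmoid logit at the last convolutional feature map,
  `α = G²/(2G² + Σ A·G³)` per pixel/channel, channel weights
  `w_c = Σ α·ReLU(G)`, map `ReLU(Σ w_c A_c)`, bilinearly upsampled and
  min-max normalized. For transformer backbones the formula is applied to
  the final patch-token grid reshaped to a spatial map. A zero-gradient
  case yields an all-zero map with a warning.
* **Saliency IoU** against the planted masks after binarizing at 0.5 of the
  normalized map (0.3/0.7 sweeps available); a both-empty comparison is
  defined as IoU 1.0. The quantitative alignment study scores the
  endoscopy and histology maps — the modalities whose lesion evidence is
  spatially localized. The CT phantom's lesion is contrast-enhancing, so a
  model may legitimately discriminate through global intensity statistics;
  its saliency map is then faithfully diffuse, and an IoU score against it
  measures the cue's spatial nature rather than saliency quality. CT maps
  are still produced and reported per case.
* **Exact Shapley attribution** over the 2³ modality coalitions with the
  zero-input baseline of the missing-modality protocol — no sampling
  approximation is needed for three players, so efficiency, null-player and
  symmetry hold to machine precision. A permutation-sampling estimator is
  included as an independent cross-check.

## Evaluation statistics

Confusion-matrix metrics (undefined denominators reported as missing, not
0), Mann–Whitney AUC with tie credit 0.5, case-level percentile bootstrap
CIs (default n = 1000), exact-binomial McNemar (χ² variant by flag),
DeLong's test via placement values, Brier score with equal-width
reliability bins, and decision-curve net benefit
`NB(t) = TP/N − (FP/N)·t/(1−t)` over thresholds 0.05–0.50 (step 0.01)
against treat-all/treat-none.

## Numerical and statistical conventions

* All arithmetic is float64 on a small numpy reverse-mode autodiff core;
  softmaxes subtract the row maximum; logarithm arguments are floored at
  1e-12; the classifier trains on the logit-space (softplus) form of the
  BCE, which is identical in value to the probability form but cannot lose
  gradients to clipping.
* Every stochastic component (generator, splits, initialization, batch
  order, dropout, bootstrap) draws from explicitly seeded generators; a
  rerun with the same configuration and seed reproduces reports byte for
  byte.
* In stochastic directional checks, AUC differences smaller than 0.005 (a
  few discordant pairs at the evaluation sizes used) are treated as ties
  rather than violations.
* Reference-experiment problem sizes — 300–400 training cases at 64 px,
  tiny backbones, 3 seeds per claim — were chosen so a full pass of all
  studies runs in minutes on one CPU core; they are stated alongside each
  result.

## Known limitations

* Desk-scale from-scratch encoders are not a statement about pretrained
  large backbones; the paper-scale preset preserves the printed
  hyperparameters but is untested here.
* Routing-weight identifiability relies on the weight-shared sum fusion; a
  concatenation-based head (kept as the static baseline) does not provide
  it.
* The exact Shapley attribution is specific to three modalities; more
  players would require the sampling estimator.
* The missing-modality protocol simulates absence by zero images, not by
  marginalizing over plausible inputs.
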