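# idfnet — interpretable dynamic fusion of trimodal imaging

`idfnet` is a research library and CLI for **dynamic multimodal fusion** in
colorectal-lesion classification. Clinical diagnosis combines endoscopy
(mucosal appearance), CT (wall structure and staging) and histopathology
(cellular morphology); each modality alone is an imperfect classifier, and
their quality varies case by case. `idfnet` fuses the three with a
dual-stage adaptive gate and makes every prediction inspectable:

* **Stage 1 — reliability gating:** each modality embedding `f_m` is scaled
  by a learned sigmoid gate `g_m = σ(w_m·f_m + b_m)` that attenuates
  unreliable inputs before any cross-modal interaction.
* **Stage 2 — entropy-regularized routing:** softmax weights
  `g_i = softmax(W_i·f̃_i + b_i)` set each modality's contribution; the
  routing entropy `H = −Σ g_i log g_i` enters the loss as a bonus so the
  model cannot collapse onto a single modality without evidence.
* **Cross-modal attention fusion:** the routed tokens interact through
  bidirectional multi-head attention; the attended tokens are summed and
  projected to the fused representation feeding a small sigmoid classifier.
* **Loss:** `L_total = L_BCE + λ·L_ent + β·L_L2` (λ = 0.01, β = 0.001).
* **Interpretability:** Grad-CAM++ saliency per modality with IoU scoring
  against lesion masks, and *exact* per-modality Shapley attribution over
  the 2³ modality coalitions (zero-input baseline).
* **Evaluation statistics:** Mann–Whitney AUC, bootstrap CIs, exact
  McNemar, DeLong, Brier/reliability curves, decision-curve analysis.

A fully seeded synthetic trimodal generator (mucosal-blob / wall-thickening
/ nuclear-density cues, pixel-accurate masks, planted per-modality
reliability, patient grouping) makes every mechanism testable end-to-end on
one CPU in minutes — no downloads, no GPU. Real datasets laid out as PNG
directories plus a CSV manifest load through the same interface. The model
itself runs on a small bundled numpy autodiff core; see
[`docs/methods.md`](docs/methods.md) for the model, the generator's design
and its limitations.

## Worked example

```bash
idfnet synth --n 400 --image-size 64 --seed 5 --out data/
idfnet train --data data/ --out run/ --config examples/desk.yaml
idfnet missing --checkpoint run/checkpoint.npz --data data/ --out missing.csv
```

which logs (abridged):

```
idfnet INFO best val AUC 0.9744 (epoch 9)
         scenario  accuracy     auc
              all     0.915 0.97975
missing_endoscopy     0.905 0.97645
       missing_ct     0.850 0.94790
missing_histology     0.500 0.88815
```

Reading: on 400 synthetic cases the trained trimodal model separates
benign from malignant with AUC 0.98. Zeroing a modality degrades
performance gracefully rather than catastrophically, and the size of each
drop tracks how much unique information that modality carried — here
histology is the most informative, exactly as the per-modality signal was
planted. Per-case explanations come from

```bash
idfnet explain --checkpoint run/checkpoint.npz --data data/ --case case00000 --out explained/
```

which writes saliency overlays (PNG), raw maps (`.npy`) and a JSON
attribution; for a correctly rejected benign case it prints

```json
{"probability": 0.1224, "baseline": 0.9997, "full": 0.1224,
 "shapley": {"ct": 0.0750, "endoscopy": -0.1906, "histology": -0.7617}, "iou": {}}
```

— the baseline is the model's output on the uninformative zero-input
reference, and the three Shapley values split the difference to the actual
prediction exactly: histology's normal nuclear density argues most strongly
against malignancy here. For malignant cases the bundle also reports the
IoU between each modality's Grad-CAM++ saliency and the planted lesion
mask (0.18–0.48 on this run's first malignant case).

The full pipeline (synth → split → train → eval → explain → report) is one
command, reproducible byte-for-byte under a fixed seed:

```bash
idfnet run --out runs/ --config examples/desk.yaml
```

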