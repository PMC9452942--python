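# sccnn — spatially constrained CNN nucleus detection for H&E histology

`sccnn` detects and classifies cell nuclei in hematoxylin-and-eosin (H&E)
stained histology tiles.  It is aimed at computational-pathology work where
the goal is a *point* annotation per nucleus (a center and a class), not a
segmentation mask: counting, density mapping, and cell-type composition
analysis of tissue images.

## The model

**Detection.**  Instead of classifying pixels, the detector regresses a
nucleus-probability surface.  For ground-truth centers z¹…zᴹ the target at
pixel z_j is

    y_j = 1 / (1 + ‖z_j − z_m*‖² / 2)    if ‖z_j − z_m*‖ ≤ d,  else 0,

where m* is the nearest center and d = 4 px — a surface that peaks at 1 on
every nucleus and is flat 0 elsewhere.  A small convolutional network
(27×27 input, conv 4×4×1×36 / pool / conv 3×3×36×48 / pool / FC 512 /
FC 512) does **not** emit this map freely.  A *parameter-estimation layer*
squashes the features into M candidate nuclei

    u_m = (H′−1)·σ(w_u·x + b_u) + 1,   v_m = (W′−1)·σ(w_v·x + b_v) + 1,
    h_m = σ(w_h·x + b_h),

and an analytic *spatial-constraint layer* renders them on the 11×11
output grid with the same kernel shape as the target, scaled by the height
h_m ∈ [0,1] (h_m = 0 switches a candidate off, so 0…M nuclei can be
represented).  Training minimizes the weighted cross-entropy
Σ_j (y_j + ε)·H(y_j, ŷ_j), with ε the nonzero-to-zero target-pixel ratio,
so the sparse peaks dominate the flat background.  Every custom layer's
analytic gradient is finite-difference checked in the test suite.

**Preprocessing.**  Input tiles are colour-deconvolved first: under the
Beer–Lambert law the optical density OD_c = −log₁₀(I_c / I₀_c) is linear in
stain concentration, so the hematoxylin (nucleus) channel is recovered by
applying the Moore–Penrose pseudo-inverse of the normalized stain matrix
(default H&E rows 0.18/0.20/0.18 and 0.01/0.13/0.01).  The detector runs on
that single concentration channel.

**Classification.**  Detected nuclei are classified into four types by a
softmax CNN on the same trunk, then refined by *adjacent-set prediction*:
each nucleus's probability vector is averaged with those of neighbouring
detections within 30 px.  Because same-type cells cluster spatially in
tissue, this ensemble suppresses isolated misclassifications.

**Synthetic scenes.**  A generator renders H&E-like tiles through the same
Beer–Lambert forward model (Gaussian hematoxylin blobs with class-dependent
size/shape/density on an eosin background, OD noise, 8-bit quantization)
with exact ground truth, so the entire pipeline trains and evaluates
end-to-end without external data.

## Worked example

```python
from sccnn import SceneSpec, TrainConfig, train_detector
from sccnn.scenes import make_training_set, simulate, hematoxylin_channel
from sccnn.detect import extract_maxima, evaluate_images

spec = SceneSpec()                      # 71x71 tiles, 8 nuclei each
patches, targets, labels, _ = make_training_set(spec, n_tiles=12, seed=1)
print(f"training set: {patches.shape[0]} patches "
      f"({(labels >= 0).sum()} nuclei, {(labels < 0).sum()} background)")
model, trace = train_detector(patches, targets, TrainConfig(), seed=1)
print(f"loss: {trace[0]:.2f} (epoch 1) -> {trace[-1]:.2f} (epoch 30)")

tile = simulate(spec, seed=778000)      # held-out tile
prob = model.predict_image(hematoxylin_channel(tile))
found = extract_maxima(prob, threshold=0.5, min_separation=4)
print(f"{len(found)} detections / {len(tile.records)} annotated nuclei")
p, r, f1 = evaluate_images({"t": found}, {"t": tile.records}, radius=6.0).pooled()
print(f"precision {p:.3f}  recall {r:.3f}  F1 {f1:.3f}")
```

Output:

```
training set: 192 patches (96 nuclei, 96 background)
loss: 32.53 (epoch 1) -> 6.67 (epoch 30)
8 detections / 8 annotated nuclei
precision 0.875  recall 0.875  F1 0.875
```

The loss drops as the parameter-estimation layer locks onto nucleus
positions; on the held-out tile, 7 of the 8 detections fall within the 6 px
matching radius of an annotated center (one is displaced further, costing
one false positive and one miss).

The same pipeline is available from the shell:

```bash
sccnn synth --out tiles --seed 3
sccnn train-detect --out model --seed 3
sccnn detect tiles/tile_000.png --checkpoint model/detector.npz --out det
sccnn eval --pred-dir det --truth-dir tiles --out report
```

## Layout

- `src/sccnn/stains.py` — Beer–Lambert model, colour deconvolution
- `src/sccnn/targets.py` — probability-map targets and annotation I/O
- `src/sccnn/layers.py`, `network.py` — numpy layers, the spatially
  constrained detector, loss, training, sliding-window inference
- `src/sccnn/detect.py` — peak picking, matching, P/R/F1 and summaries
- `src/sccnn/classify.py` — softmax CNN, adjacent-set prediction, AUC/F1
- `src/sccnn/scenes.py` — synthetic H&E scene generator
- `src/sccnn/experiments.py` — canonical desk-scale experiments
- `src/sccnn/cli.py`, `config.py` — command-line pipeline and strict config
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
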