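# busfeat

Quantitative analysis of breast-ultrasound (BUS) lesions: level-set
segmentation, four handcrafted "characteristic features" that mirror the
sonographic signs radiologists read, and an RBF-SVM classifier for
benign-vs-malignant decision support. A seeded ultrasound-phantom generator
makes the whole pipeline testable without clinical data.

## Who this is for

Researchers in computer-aided diagnosis who want a transparent, fully
inspectable baseline: every feature is a closed-form quantity with a
clinical interpretation, in contrast to end-to-end deep models. Externally
computed deep-feature vectors (e.g. from a CNN embedding) can be fused with
the handcrafted features, but no network inference happens here.

## The method

1. **Segmentation — DRLSE.** The lesion contour is the zero level of a
   field φ evolved by distance-regularized level-set evolution:

       E(φ) = μ ∫ p(|∇φ|) + λ ∫ g δ(φ) |∇φ| + α ∫ g H(−φ)

   with the double-well potential p (no reinitialization needed), the edge
   indicator g = 1/(1 + |∇(G_σ∗I)|²) and smoothed Heaviside/Dirac H, δ.
   A negative α inflates an interior seed until g stops it at the lesion
   margin; evolution halts when the zero-crossing pixel set is stable.

2. **Characteristic features (CF).** From the contour's four extreme
   points (top/bottom/left/right):
   - **orientation** = height/width — taller-than-wide is a malignancy sign;
   - **EI score** — mean row/column standard deviations of 21×15 patches at
     the top and bottom vertices; blurred (indistinct) margins score lower;
   - **PS score** = −log₁₀(η₂₀ + η₀₂), the first Hu moment of the region
     under the lesion (8-bit intensity scale), summarizing posterior
     acoustic shadowing;
   - **SC score** — slope b of the Richardson (divider) plot
     log₁₀N(R) = a + b·log₁₀R obtained by stepping circles of radius
     R ∈ {4…11} px along the contour; more negative slope = more complex
     (spiculated) margin.

3. **Classification.** CF (optionally concatenated with deep features) is
   min-max normalized (SC inverted) and fed to a soft-margin RBF-SVM;
   c and the kernel width g are chosen by seeded, stratified 3-fold
   grid-search cross-validation. Reported metrics: sensitivity,
   specificity, accuracy, precision, F1, ROC/AUC (malignant = positive).

## Worked example

```python
import numpy as np, busfeat as bf
from busfeat.io import _seed_from_mask

spec = bf.PhantomSpec(seed=8, aspect=0.95, irregularity_amp=0.25,
                      speckle_looks=4.0, base_radius=20.0,
                      shadow_enabled=True, shadow_strength=0.3)
image, mask, _ = bf.generate_phantom(spec)           # malignant-like phantom
contour, seg, iters = bf.segment_lesion(image, _seed_from_mask(mask))
cf = bf.characteristic_features(image, contour)
print(iters, cf)
```

prints (Dice vs ground truth 0.930, converged in 540 iterations):

```
orientation=0.902  ei_score=0.232  ps_score=2.887  sc_score=-1.070
```

Orientation ≈ 0.9 (nearly as tall as wide) and the SC slope −1.07 (well
below the −1.0 of a smooth outline) are exactly the malignant-type signals;
a benign-like phantom (aspect 0.55, smooth margin) under the same pipeline
gives orientation 0.641 and SC −1.009.

The same steps are available from the shell:

```bash
busfeat phantom --out img.png --mask mask.png --seed 8 --aspect 0.95 \
        --irregularity 0.25 --shadow 0.3
busfeat segment --image img.png --seed 54,52,74,72 \
        --out-mask seg.png --out-contour contour.csv
busfeat features --image img.png --contour contour.csv --out features.csv
busfeat run --out results/        # full cohort: generate, segment, train, evaluate
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the complete pipeline end to end — generates a 40-phantom cohort
(20 benign-like, 20 malignant-like), segments every image with DRLSE,
computes the four characteristic features, grid-searches and trains the
SVM on a stratified half, and prints the held-out confusion counts and
metrics — then writes the results JSON to `--out`.

## Layout

- `src/busfeat/phantom.py` — synthetic speckled lesion images with known
  geometry (ground-truth mask + contour)
- `src/busfeat/segmentation.py` — DRLSE: edge indicator, evolution,
  contour extraction
- `src/busfeat/features.py` — orientation, EI, PS (Hu moment), SC (divider
  method)
- `src/busfeat/classify.py` — normalization, fusion, SVM grid search,
  metrics
- `src/busfeat/io.py`, `cli.py` — file formats, run config, pipeline, CLI
- `docs/methods.md` — model assumptions, parameter defaults, numerical
  choices, limitations
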