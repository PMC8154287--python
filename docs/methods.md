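# Methods

This note documents the models behind `busfeat`, the parameter defaults and
why they hold, what the phantom generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## 1. Phantom generator

The generator renders a single hypoechoic lesion in a speckled background —
the minimal stated world in which segmentation and feature scoring can be
validated against known geometry.

**Boundary model.** The lesion boundary is polar:
r(θ) = E(θ) · (1 + A·P(θ)), where E is the ellipse with horizontal
semi-axis `base_radius` and vertical semi-axis `aspect·base_radius`, and
P(θ) is a sum of `irregularity_harmonics` sinusoids (random phases from the
seed) normalized by its own peak, so `A = irregularity_amp` is exactly the
maximum relative radial deviation. Harmonic wavenumbers run from 4 upward:
wavenumbers 2–3 would mimic global elongation and triangularity, which are
the province of `aspect`, whereas margin spiculation — the clinical sign
the shape-complexity score targets — is fine-scale. With the default count
(12) the perturbation wavelengths (≈10–38 px at the default radius) span
the divider radii 4–11 px, so the SC slope responds monotonically to `A`.
The invariant `A ≤ 0.5` guarantees r > 0.

**Image model.** background − lesion step (0.65 vs 0.25) → Gaussian blur of
width `edge_blur_sigma` (margin indistinctness) → multiplicative posterior
shadow (rectangular band below the lesion spanning its horizontal extent,
linear horizontal taper, peak attenuation `shadow_strength`) →
multiplicative speckle, a Gamma(shape = `speckle_looks`, mean 1) factor —
the standard fully-developed-speckle approximation for amplitude-detected
ultrasound — → clip to [0, 1]. Four looks emulates moderate compounding.

**Not emulated:** depth-dependent attenuation and focusing, refraction and
edge shadows, real tissue texture (spatially correlated speckle), operator
variability, multiple or non-lesion structures. A green phantom test
therefore establishes algorithmic correctness on controlled geometry, not
clinical performance.

**Presets.** `benign_spec` draws aspect 0.45–0.65, irregularity ≤ 0.05,
blur 0.6–1.2 px, no shadow; `malignant_spec` draws aspect 0.85–1.05,
irregularity 0.2–0.28, blur 1.0–1.8 px, shadow 0.2–0.35. The blur cap at
1.8 px is deliberate: at a 20 px lesion radius, a 3 px Gaussian erases the
edge rather than blurring it, which no edge-based segmentation can recover
and which does not correspond to a readable clinical image.

## 2. DRLSE segmentation

Gradient flow (explicit Euler, time step τ):

∂φ/∂t = μ·div(d_p(|∇φ|)∇φ) + λ·δ_ε(φ)·div(g∇φ/|∇φ|) + α·g·δ_ε(φ)

with the double-well potential p (minima at |∇φ| = 0 and 1), so flat
regions far from the interface stay flat and a unit-gradient band is a
fixed point — no reinitialization. δ_ε and H_ε are the compact-support
cosine forms of half-width ε.

**Defaults** (all in `DRLSEParams`, overridable via YAML config):

| parameter | default | rationale |
|---|---|---|
| μ (regularization) | 0.2 | μτ = 0.2 < 0.25 satisfies the explicit-diffusion stability bound |
| τ (time step) | 1.0 | largest stable step at μ = 0.2 |
| λ (edge/length) | 5.0 | standard weighting that makes the geodesic term dominate near edges |
| α (balloon) | −2.0 | expands an interior seed; −3 was found to leak through blurred speckled edges on ~30 % of malignant-like phantoms, −2 segments all presets (Dice ≥ 0.88) |
| ε (H/δ width) | 1.5 px | standard compact-support width |
| c0 (init step) | 2.0 | > ε, so the delta terms are inactive until the regularizer builds a band |
| σ_g (edge smoothing) | 1.5 px | suppresses 4-look speckle without displacing the lesion edge |
| grad_scale | 100 | see below |
| max_iters / zc_window | 1000 / 10 | phantom-scale budget; stop when the zero-crossing pixel set is unchanged for 10 checks spaced 10 iterations |

**Edge-indicator scale.** g = 1/(1 + |∇(G_σ∗(s·I))|²) with s =
`grad_scale`. The indicator has no intrinsic intensity scale: on a [0, 1]
image the squared gradient is ~10⁻², g never leaves ≈1, and the balloon
force never stops; on the raw 8-bit scale (s = 255) the g-valley around a
blurred edge is so wide and flat that the front stalls ~1.5 px inside the
true boundary. s = 100 places lesion-edge g near 10⁻², which both arrests
the balloon and keeps the valley narrow; it was selected by a sweep over
mixed phantoms (Dice min/mean 0.92/0.95, vs 0.37/0.66 at 255 with α = −2).
Because `segment_lesion` first affinely normalizes the image to [0, 1],
segmentation is invariant to constant intensity rescaling of the input.

**Stopping and extraction.** The mask is the largest connected component
of {φ < 0}; the contour is the sub-pixel zero level set around that
component (marching squares), returned closed and screen-counter-clockwise.
Collapse of the zero level set raises an error suggesting a smaller |α|.
Updates are full-grid: at 128–512 px scale a narrowband brings no
measurable benefit and full-grid keeps the update exactly reproducible.

## 3. Characteristic features

**Extreme points.** Ties along a flat extreme (e.g. the top side of a
square) resolve to the midpoint of the longest contiguous run, matching the
tangent-line construction of an extreme region.

**Orientation** = |y_top − y_bottom| / (x_right − x_left) in the y-down
pixel convention; positive by construction, scale- and
translation-invariant.

**EI score.** 21-row × 15-column patches centered on the top and bottom
vertices (the longer side spans the edge vertically); per-patch score
max(mean column std, mean row std) with population standard deviations;
final score = mean of the two patches. Centered placement (rather than
offset outward) was chosen; with a centered patch half the rows sample each
side of the edge, maximizing sensitivity to the transition width.

**PS score.** Rectangle below the lesion, x ∈ [x_l, x_r],
depth = lesion height ("auto"), clipped at the image bottom; a lesion
touching the bottom edge has no posterior region (error). Moments use
1-based pixel coordinates; η_pq = μ_pq/μ₀₀^ρ with ρ = (p+q)/2 + 1; the
score is −sign(η₂₀+η₀₂)·log₁₀|η₂₀+η₀₂|. The region is scored on the 8-bit
intensity scale (crop × 255): for a roughly uniform region
η₂₀+η₀₂ ≈ (M²+N²)/(12·mean·MN), i.e. inversely proportional to the mean
intensity, so the familiar clinical score range (≈2–3) exists only on
8-bit values — on [0, 1] intensities every region would score ≈0.5.
Because of that same 1/mean scaling, inputs must be consistently
normalized; the image loader enforces division by the dtype maximum.

**SC score.** The contour is resampled to uniform arc length
(spacing = min(R)/8), the walk starts at the top vertex, and each step
advances to the first forward intersection of the circle of radius R with
the contour, found by exact segment–circle root finding; the final partial
step counts as one (cartographer convention). N(R) over R ∈ {4…11} px is
fitted by ordinary least squares on (log₁₀R, log₁₀N); the slope is the
score. On a circle the implementation matches the chord-angle closed form
N = ⌈2π/(2·asin(R/2ρ))⌉ within one count.

A failed component aborts the whole feature vector by default ("fail
loudly"): silently missing features would corrupt a cohort table.

## 4. Classification

Min-max normalization is fitted on training data only, with an explicit
per-feature direction — standard for orientation, EI, PS and any deep
features; inverted for SC, where more negative means more complex. Test
values outside the training range extrapolate linearly (the map stays
affine) and are logged rather than clipped. Fusion is serial: the 4 CF
values followed by any external deep-feature vector.

The SVM uses the Gaussian kernel exp(−g‖u−v‖²); c and g are selected on a
powers-of-two grid (2⁻⁵…2⁵) by stratified, seeded 3-fold cross-validation;
ties break toward the smallest c, then the smallest g (prefer the simpler
model). Malignant = 1 is the positive class throughout; ratios with a zero
denominator (e.g. precision without positive predictions) are reported as
missing, never as 0. AUC is the trapezoidal area under the full-sweep ROC,
which equals the rank statistic with ties averaged.

## 5. Known limitations

- The phantom world is far easier than clinical BUS; held-out phantom
  accuracy (~0.95–1.0 on 40-image cohorts) says nothing about clinical
  accuracy.
- DRLSE needs a user seed inside the lesion and a detectable edge; margins
  blurred beyond ≈2 px at 20 px lesion scale cause stalls or leaks.
- Orientation read from a segmented contour under speckle carries a small
  outward bias at the extreme points (individual errors up to ≈0.08 at
  4 looks; unbiased in the mean to ≤0.05).
- The divider counts are integers; the fitted slope carries quantization
  noise of ≈±0.015, which sets the resolution at which shape complexity
  can be distinguished.
- Deep features are ingested only as precomputed per-image vectors; no
  network inference is performed.
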