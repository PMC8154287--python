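"""Synthetic ultrasound-like phantom generator.

Produces 2D grayscale images containing a single hypoechoic (darker than
background) lesion with controllable geometry, so the segmentation and
feature stages can be exercised without clinical data.  The lesion boundary
is a perturbed ellipse in polar form; the image model is

    base intensity  ->  Gaussian edge blur  ->  posterior shadow band
                    ->  multiplicative speckle  ->  clip to [0, 1]

Speckle follows the fully-developed approximation: a Gamma-distributed
multiplicative factor with mean 1 and shape ``speckle_looks`` (larger looks
= less variance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon2mask

__all__ = ["PhantomSpec", "generate_phantom", "benign_spec", "malignant_spec"]


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic image.

    Attributes
    ----------
    rows, cols : int
        Image size in pixels.
    center : tuple[float, float]
        Lesion center as (row, col).
    base_radius : float
        Horizontal semi-axis of the unperturbed lesion, pixels.
    aspect : float
        Height/width ratio of the lesion (vertical semi-axis =
        ``aspect * base_radius``).
    irregularity_amp : float
        Relative boundary perturbation amplitude, in [0, 0.5].
    irregularity_harmonics : int
        Number of sinusoidal harmonics in the boundary perturbation.
    edge_blur_sigma : float
        Gaussian blur width applied to the ideal binary scene, pixels.
    lesion_intensity, background_intensity : float
        Mean intensities in [0, 1]; the lesion must be darker.
    speckle_looks : float
        Shape of the mean-1 Gamma speckle factor; 0 disables speckle.
    shadow_strength : float
        Peak attenuation of the posterior band, in [0, 1].
    shadow_enabled : bool
        Whether the posterior shadow band is applied.
    seed : int
        Seed for the phantom's private random generator.
    """

    rows: int = 128
    cols: int = 128
    center: tuple[float, float] = (56.0, 64.0)
    base_radius: float = 24.0
    aspect: float = 1.0
    irregularity_amp: float = 0.0
    irregularity_harmonics: int = 12
    edge_blur_sigma: float = 1.0
    lesion_intensity: float = 0.25
    background_intensity: float = 0.65
    speckle_looks: float = 0.0
    shadow_strength: float = 0.0
    shadow_enabled: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.base_radius <= 0:
            raise ValueError("base_radius must be positive")
        if not (0.0 <= self.irregularity_amp <= 0.5):
            raise ValueError("irregularity_amp must lie in [0, 0.5]")
        if self.aspect <= 0:
            raise ValueError("aspect must be positive")
        if self.speckle_looks < 0:
            raise ValueError("speckle_looks must be >= 0")
        if not (0.0 <= self.shadow_strength <= 1.0):
            raise ValueError("shadow_strength must lie in [0, 1]")
        # Lesion (worst-case radius) plus 3-sigma blur support must stay inside.
        r_max = self.base_radius * max(1.0, self.aspect) * (1.0 + self.irregularity_amp)
        margin = 3.0 * self.edge_blur_sigma
        cr, cc = self.center
        for name, lo, hi, c in (
            ("top", 0.0, self.rows - 1.0, cr),
            ("left", 0.0, self.cols - 1.0, cc),
        ):
            if c - r_max - margin < lo:
                raise ValueError(
                    f"lesion violates the {name} margin: needs "
                    f"{r_max + margin:.1f} px, has {c - lo:.1f}"
                )
        if cr + r_max + margin > self.rows - 1:
            raise ValueError(
                f"lesion violates the bottom margin: needs "
                f"{r_max + margin:.1f} px, has {self.rows - 1 - cr:.1f}"
            )
        if cc + r_max + margin > self.cols - 1:
            raise ValueError(
                f"lesion violates the right margin: needs "
                f"{r_max + margin:.1f} px, has {self.cols - 1 - cc:.1f}"
            )


def boundary_radius(spec: PhantomSpec, theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Polar radius r(θ) of the lesion boundary.

    θ is measured from the +x (column) axis with y pointing down.  The base
    shape is the ellipse with horizontal semi-axis ``base_radius`` and
    vertical semi-axis ``aspect * base_radius``; the perturbation is a sum of
    ``irregularity_harmonics`` sinusoids with seeded random phases, scaled so
    ``irregularity_amp`` bounds the relative deviation.
    """
    a = spec.base_radius
    b = spec.base_radius * spec.aspect
    ellipse = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    n_harm = max(int(spec.irregularity_harmonics), 0)
    if spec.irregularity_amp == 0.0 or n_harm == 0:
        return ellipse
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_harm)
    # wavenumbers start at 4: 2-3 would mimic global elongation/triangularity
    # (already set by `aspect`); margin irregularity is finer-scale
    ks = np.arange(4, 4 + n_harm)

    def harmonic_sum(t: np.ndarray) -> np.ndarray:
        return np.sum(np.sin(np.outer(t, ks) + phases), axis=1)

    # normalize by the sum's peak so irregularity_amp is exactly the maximum
    # relative radial deviation (keeps r > 0 for amp <= 0.5)
    dense = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
    peak = np.abs(harmonic_sum(dense)).max()
    pert = harmonic_sum(theta) / peak
    return ellipse * (1.0 + spec.irregularity_amp * pert)


def _true_contour(spec: PhantomSpec, rng: np.random.Generator, n_theta: int = 720) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    r = boundary_radius(spec, theta, rng)
    cr, cc = spec.center
    x = cc + r * np.cos(theta)
    y = cr + r * np.sin(theta)
    return np.column_stack([x, y])


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a phantom image.

    Returns
    -------
    image : (rows, cols) float array in [0, 1]
    mask : (rows, cols) bool array, the ground-truth lesion support
    contour : (V, 2) float array of (x, y) vertices of the true boundary,
        ordered by polar angle (closed implicitly).

    Identical ``spec`` (including seed) gives bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    contour = _true_contour(spec, rng)

    # polygon2mask wants (row, col) vertex order
    mask = polygon2mask((spec.rows, spec.cols), contour[:, ::-1])

    image = np.full((spec.rows, spec.cols), spec.background_intensity, dtype=float)
    image[mask] = spec.lesion_intensity

    if spec.edge_blur_sigma > 0:
        image = gaussian_filter(image, spec.edge_blur_sigma)

    if spec.shadow_enabled and spec.shadow_strength > 0:
        image *= _shadow_profile(spec, contour)

    if spec.speckle_looks > 0:
        factor = rng.gamma(shape=spec.speckle_looks, scale=1.0 / spec.speckle_looks, size=image.shape)
        image = image * factor

    return np.clip(image, 0.0, 1.0), mask, contour


def _shadow_profile(spec: PhantomSpec, contour: np.ndarray) -> np.ndarray:
    """Multiplicative field: 1 everywhere except the band under the lesion.

    The band spans the lesion's horizontal extent from its lowest point to
    the image bottom; attenuation is maximal at the band's center column and
    tapers linearly to zero at its left/right edges.
    """
    x_min, x_max = contour[:, 0].min(), contour[:, 0].max()
    y_bottom = contour[:, 1].max()
    profile = np.ones((spec.rows, spec.cols), dtype=float)
    cols = np.arange(spec.cols, dtype=float)
    half = (x_max - x_min) / 2.0
    cx = (x_max + x_min) / 2.0
    taper = np.clip(1.0 - np.abs(cols - cx) / half, 0.0, 1.0)
    row0 = int(np.ceil(y_bottom))
    if row0 < spec.rows:
        profile[row0:, :] = 1.0 - spec.shadow_strength * taper[None, :]
    return profile


def benign_spec(seed: int, **overrides) -> PhantomSpec:
    """Benign-like preset: wider than tall, smooth margin, sharp edge."""
    rng = np.random.default_rng(seed)
    params = dict(
        aspect=float(rng.uniform(0.45, 0.65)),
        irregularity_amp=float(rng.uniform(0.0, 0.05)),
        edge_blur_sigma=float(rng.uniform(0.6, 1.2)),
        shadow_enabled=False,
        speckle_looks=4.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    params.update(overrides)
    return PhantomSpec(**params)


def malignant_spec(seed: int, **overrides) -> PhantomSpec:
    """Malignant-like preset: taller, irregular, blurred margin, shadowed."""
    rng = np.random.default_rng(seed)
    params = dict(
        aspect=float(rng.uniform(0.85, 1.05)),
        irregularity_amp=float(rng.uniform(0.2, 0.28)),
        edge_blur_sigma=float(rng.uniform(1.0, 1.8)),
        shadow_enabled=True,
        shadow_strength=float(rng.uniform(0.2, 0.35)),
        speckle_looks=4.0,
        base_radius=20.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    params.update(overrides)
    return PhantomSpec(**params)
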