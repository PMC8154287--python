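"""Handcrafted characteristic features of a segmented lesion.

Four scores summarize the sonographic signs radiologists read from a
breast-ultrasound lesion:

orientation
    Height/width ratio of the contour bounding box; taller-than-wide lesions
    are associated with malignancy.
EI (edge indistinctness)
    Intensity variability in patches cut around the top and bottom contour
    vertices; sharp margins give large row/column standard deviations,
    blurred ones small.
PS (posterior shadowing)
    The first Hu moment (eta20 + eta02) of the region under the lesion,
    log-transformed; darker, more structured shadow bands change the score.
SC (shape complexity)
    Slope of the Richardson (divider) plot log10 N(R) vs log10 R obtained by
    stepping circles of radius R along the contour; more negative slope
    means a more complex (fractal) margin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ContourExtremes",
    "EIPatch",
    "MomentSet",
    "DividerTrace",
    "SCFit",
    "CharacteristicFeatures",
    "FeatureConfig",
    "contour_extremes",
    "orientation_score",
    "ei_patch",
    "ei_score_patch",
    "ei_score",
    "ps_region",
    "hu_ps_score",
    "divider_counts",
    "sc_score",
    "characteristic_features",
]


# ---------------------------------------------------------------- types

@dataclass(frozen=True)
class ContourExtremes:
    """Top/bottom/leftmost/rightmost contour points, (x, y), y down."""

    top: tuple[float, float]
    bottom: tuple[float, float]
    leftmost: tuple[float, float]
    rightmost: tuple[float, float]


@dataclass(frozen=True)
class EIPatch:
    """An m-row x n-column intensity crop around one contour vertex."""

    values: np.ndarray
    provenance: str  # "top" or "bottom"


@dataclass(frozen=True)
class MomentSet:
    """Raw, central and normalized central moments of a region (order <= 2)."""

    m00: float
    centroid: tuple[float, float]
    mu20: float
    mu02: float
    eta20: float
    eta02: float


@dataclass(frozen=True)
class DividerTrace:
    """(R, N(R)) pairs from walking circles of radius R along the contour."""

    radii: tuple[float, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        r = np.asarray(self.radii)
        n = np.asarray(self.counts)
        if np.any(np.diff(r) <= 0):
            raise ValueError("radii must be strictly increasing")
        if np.any(n <= 0):
            raise ValueError("counts must be positive")


@dataclass(frozen=True)
class SCFit:
    """Least-squares line log10 N = a + b log10 R; the slope b is the score."""

    intercept: float
    slope: float
    rss: float


@dataclass(frozen=True)
class CharacteristicFeatures:
    orientation: float
    ei_score: float
    ps_score: float
    sc_score: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.orientation, self.ei_score, self.ps_score, self.sc_score]
        )

    NAMES = ("orientation", "ei_score", "ps_score", "sc_score")


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable feature parameters (patch size, divider radii, PS depth)."""

    ei_rows: int = 21            # m, patch height
    ei_cols: int = 15            # n, patch width
    radii: tuple[float, ...] = (4, 5, 6, 7, 8, 9, 10, 11)
    ps_depth: float | str = "auto"  # pixels, or "auto" = lesion height


# ---------------------------------------------------------------- extremes

def _extreme_run_midpoint(contour: np.ndarray, coord: int, kind: str,
                          tol: float = 1e-6) -> tuple[float, float]:
    """Midpoint of the contiguous vertex run attaining an extreme coordinate.

    ``coord`` is 0 for x, 1 for y; ``kind`` is "min" or "max".  Ties (a flat
    side of the contour touching the extreme line) are resolved by the
    midpoint of the run, mirroring a tangent line touching a flat extreme.
    """
    vals = contour[:, coord]
    ext = vals.min() if kind == "min" else vals.max()
    hit = np.abs(vals - ext) <= tol
    idx = np.flatnonzero(hit)
    if len(idx) == 1:
        return tuple(contour[idx[0]])
    # group into runs, contiguous modulo the closed contour
    n = len(contour)
    runs: list[list[int]] = [[idx[0]]]
    for i in idx[1:]:
        if i == runs[-1][-1] + 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    if len(runs) > 1 and runs[0][0] == 0 and runs[-1][-1] == n - 1:
        runs[0] = runs.pop() + runs[0]
    run = max(runs, key=len)
    mid = (contour[run[0]] + contour[run[-1]]) / 2.0
    return (float(mid[0]), float(mid[1]))


def contour_extremes(contour: np.ndarray) -> ContourExtremes:
    """Locate the four extreme contour points (Fig.-4-style tangent points)."""
    contour = np.asarray(contour, dtype=float)
    if len(contour) < 8:
        raise ValueError("contour needs at least 8 vertices")
    if np.ptp(contour[:, 0]) <= 0 or np.ptp(contour[:, 1]) <= 0:
        raise ValueError("degenerate contour: zero width or height")
    return ContourExtremes(
        top=_extreme_run_midpoint(contour, 1, "min"),
        bottom=_extreme_run_midpoint(contour, 1, "max"),
        leftmost=_extreme_run_midpoint(contour, 0, "min"),
        rightmost=_extreme_run_midpoint(contour, 0, "max"),
    )


def orientation_score(extremes: ContourExtremes) -> float:
    """Lesion height / width, always positive (y grows downward)."""
    width = extremes.rightmost[0] - extremes.leftmost[0]
    if width <= 0:
        raise ValueError("zero-width contour")
    return abs(extremes.top[1] - extremes.bottom[1]) / width


# ---------------------------------------------------------------- EI score

def ei_patch(image: np.ndarray, vertex: tuple[float, float], m: int = 21,
             n: int = 15, provenance: str = "") -> EIPatch:
    """Exact m x n crop centered on ``vertex`` (x, y); errors at borders."""
    rows, cols = image.shape
    cx, cy = int(round(vertex[0])), int(round(vertex[1]))
    r0 = cy - m // 2
    c0 = cx - n // 2
    r1, c1 = r0 + m, c0 + n
    for side, bad in (("top", r0 < 0), ("bottom", r1 > rows),
                      ("left", c0 < 0), ("right", c1 > cols)):
        if bad:
            raise ValueError(f"EI patch exceeds the image on the {side} side")
    return EIPatch(values=np.asarray(image[r0:r1, c0:c1], dtype=float),
                   provenance=provenance)


def ei_score_patch(patch: EIPatch) -> float:
    """max(x_std, y_std): mean column std vs mean row std (population form)."""
    v = patch.values
    x_std = float(np.mean(np.std(v, axis=0)))  # per-column stds, averaged
    y_std = float(np.mean(np.std(v, axis=1)))  # per-row stds, averaged
    return max(x_std, y_std)


def ei_score(image: np.ndarray, extremes: ContourExtremes, m: int = 21,
             n: int = 15) -> float:
    """Average of the EI scores of the top-vertex and bottom-vertex patches."""
    up = ei_score_patch(ei_patch(image, extremes.top, m, n, "top"))
    down = ei_score_patch(ei_patch(image, extremes.bottom, m, n, "bottom"))
    return 0.5 * (up + down)


# ---------------------------------------------------------------- PS score

def ps_region(image: np.ndarray, extremes: ContourExtremes,
              depth: float | str = "auto") -> np.ndarray:
    """Rectangle under the lesion: x in [x_l, x_r], y in [y_d, y_d + depth].

    ``depth="auto"`` uses the lesion height (y_d - y_u).  The region is
    clipped at the image bottom; a lesion touching the bottom edge has no
    posterior region and is an error.

    The returned crop is on the conventional 8-bit intensity scale
    (the [0, 1] image times 255).  The normalized moment sum eta20 + eta02
    of a roughly uniform region is ~(M^2+N^2)/(12*mean*M*N), i.e. inversely
    proportional to the mean intensity, so the familiar clinical PS-score
    range (roughly 2-3) only arises on 8-bit values; on a [0, 1] image every
    region would score near 0.5 regardless of shadow content.
    """
    rows, cols = image.shape
    x_l = int(np.floor(extremes.leftmost[0]))
    x_r = int(np.ceil(extremes.rightmost[0]))
    y_d = int(np.ceil(extremes.bottom[1]))
    if depth == "auto":
        depth = extremes.bottom[1] - extremes.top[1]
    y_end = int(min(y_d + float(depth), rows))
    if y_d >= rows - 1 or y_end <= y_d:
        raise ValueError("lesion reaches the image bottom: no posterior region")
    crop = np.asarray(image[y_d:y_end, max(x_l, 0):min(x_r + 1, cols)], dtype=float)
    return crop * 255.0


def region_moments(region: np.ndarray) -> MomentSet:
    """Raw/central/normalized moments with 1-based pixel coordinates."""
    f = np.asarray(region, dtype=float)
    n_rows, n_cols = f.shape
    x = np.arange(1, n_cols + 1, dtype=float)[None, :]
    y = np.arange(1, n_rows + 1, dtype=float)[:, None]
    m00 = float(f.sum())
    if m00 <= 0:
        raise ValueError("region has zero intensity mass (m00 = 0)")
    xbar = float((x * f).sum()) / m00
    ybar = float((y * f).sum()) / m00
    mu20 = float(((x - xbar) ** 2 * f).sum())
    mu02 = float(((y - ybar) ** 2 * f).sum())
    rho = 2.0  # (p + q) / 2 + 1 with p + q = 2
    eta20 = mu20 / m00**rho
    eta02 = mu02 / m00**rho
    return MomentSet(m00=m00, centroid=(xbar, ybar), mu20=mu20, mu02=mu02,
                     eta20=eta20, eta02=eta02)


def hu_ps_score(region: np.ndarray) -> float:
    """-sign(s) * log10 |s| with s = eta20 + eta02 (the first Hu moment)."""
    mom = region_moments(region)
    s = mom.eta20 + mom.eta02
    if s == 0:
        raise ValueError("eta20 + eta02 is zero; log-transform undefined")
    return float(-np.sign(s) * np.log10(abs(s)))


# ---------------------------------------------------------------- SC score

def _resample_closed(contour: np.ndarray, spacing: float) -> tuple[np.ndarray, float]:
    """Uniform arc-length resampling of a closed polyline; returns (pts, L)."""
    pts = np.asarray(contour, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    length = float(seg.sum())
    n = max(int(np.ceil(length / spacing)), 16)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, length, n, endpoint=False)
    x = np.interp(t, s, closed[:, 0])
    y = np.interp(t, s, closed[:, 1])
    return np.column_stack([x, y]), length


def _circle_exit_root(a: np.ndarray, b: np.ndarray, center: np.ndarray,
                      radius: float) -> float:
    """u in (0, 1] where |a + u(b-a) - center| = radius (inside-to-outside)."""
    d = b - a
    f = a - center
    qa = float(d @ d)
    qb = 2.0 * float(f @ d)
    qc = float(f @ f) - radius**2
    disc = qb**2 - 4.0 * qa * qc
    if disc < 0 or qa == 0:
        return 1.0
    u = (-qb + np.sqrt(disc)) / (2.0 * qa)
    return float(np.clip(u, 0.0, 1.0))


def divider_counts(contour: np.ndarray, radii=(4, 5, 6, 7, 8, 9, 10, 11),
                   start: str = "top") -> DividerTrace:
    """Richardson divider walk: count circles of each radius along the contour.

    Starting from the top vertex, repeatedly advance to the first forward
    intersection of the circle of radius R (centered at the current point)
    with the contour; N(R) is the number of steps needed to return to or
    pass the start, the final partial step counting as one (cartographer
    convention).  The contour is resampled to uniform arc length first and
    the intersection is located by exact segment-circle root finding.
    """
    contour = np.asarray(contour, dtype=float)
    radii = tuple(float(r) for r in radii)
    extent = max(np.ptp(contour[:, 0]), np.ptp(contour[:, 1]))
    for r in radii:
        if r >= extent:
            raise ValueError(f"radius {r} exceeds the contour extent {extent:.1f}")
    spacing = min(radii) / 8.0
    pts, length = _resample_closed(contour, spacing)
    if start == "top":
        start_idx = int(np.argmin(pts[:, 1]))
    else:
        raise ValueError(f"unknown start point {start!r}")
    pts = np.roll(pts, -start_idx, axis=0)
    # unroll twice so a full walk never needs modular arithmetic
    ext = np.vstack([pts, pts, pts[:1]])
    seg = np.linalg.norm(np.diff(ext, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])

    counts = []
    for r in radii:
        t = 0.0
        center = ext[0].copy()
        steps = 0
        while t < length:
            j = int(np.searchsorted(s, t, side="right"))
            while j < len(ext) and np.linalg.norm(ext[j] - center) < r:
                j += 1
            if j >= len(ext):
                steps += 1  # closing partial step
                t = length
                break
            # crossing lies on the sub-segment from the current position
            # (possibly mid-segment) to vertex j
            t_a = max(s[j - 1], t)
            frac = 0.0 if seg[j - 1] == 0 else (t_a - s[j - 1]) / seg[j - 1]
            a = ext[j - 1] + frac * (ext[j] - ext[j - 1])
            u = _circle_exit_root(a, ext[j], center, r)
            center = a + u * (ext[j] - a)
            t = t_a + u * float(np.linalg.norm(ext[j] - a))
            steps += 1
        counts.append(steps)
    return DividerTrace(radii=radii, counts=tuple(counts))


def sc_score(trace: DividerTrace) -> SCFit:
    """OLS fit of log10 N(R) on log10 R; the slope is the SC score."""
    if len(trace.radii) < 3:
        raise ValueError("need at least 3 (R, N) pairs to fit a slope")
    lx = np.log10(np.asarray(trace.radii, dtype=float))
    ly = np.log10(np.asarray(trace.counts, dtype=float))
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (intercept + slope * lx)
    return SCFit(intercept=float(intercept), slope=float(slope),
                 rss=float(np.sum(resid**2)))


# ---------------------------------------------------------------- assembly

def characteristic_features(image: np.ndarray, contour: np.ndarray,
                            config: FeatureConfig | None = None) -> CharacteristicFeatures:
    """Compute the 4-score CF vector (orientation, EI, PS, SC) for one image.

    Components fail loudly: any error in a single feature aborts the whole
    computation (a lesion whose posterior region is missing, for instance,
    cannot be scored consistently with the rest of a cohort).
    """
    cfg = config or FeatureConfig()
    extremes = contour_extremes(contour)
    orient = orientation_score(extremes)
    ei = ei_score(image, extremes, cfg.ei_rows, cfg.ei_cols)
    ps = hu_ps_score(ps_region(image, extremes, cfg.ps_depth))
    sc = sc_score(divider_counts(contour, cfg.radii)).slope
    return CharacteristicFeatures(orientation=orient, ei_score=ei,
                                  ps_score=ps, sc_score=sc)
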