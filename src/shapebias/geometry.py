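"""Contour geometry: extraction, resampling, curvature, and elliptic Fourier shape.

All coordinates are 0-based ``(row, col)`` floats with rows increasing
downward.  Contours are closed simple polylines stored as ``(n, 2)`` arrays
whose first vertex is *not* repeated at the end, oriented counterclockwise
under the image convention (positive shoelace area with ``x = col``,
``y = -row``).

Two complementary shape summaries are provided:

* *global shape* — normalized elliptic Fourier descriptors of the bounding
  contour (low harmonics capture the overall configuration of parts);
* *local contour features* — arc-length-weighted histograms of signed
  curvature (turning angle per unit arc length) along the contour.

These operationalize the global-shape vs local-edge-feature contrast used
throughout the stimulus manipulations in :mod:`shapebias.stimuli`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage import draw as _draw
from skimage import measure as _measure

__all__ = [
    "CurvatureProfile",
    "ShapeDescriptor",
    "ManipulationReport",
    "default_curvature_bins",
    "extract_contour",
    "contour_length",
    "signed_area",
    "resample_arclength",
    "smooth_contour",
    "curvature_profile",
    "elliptic_fourier",
    "global_shape_distance",
    "gauge_flip",
    "curvature_histogram",
    "local_feature_distance",
    "rasterize",
    "mask_curvature_histogram",
    "log_curvature_bins",
]

#: Default smoothing of raster staircase, in pixels of arc length.
DEFAULT_SMOOTH_PX = 2.0
#: Default number of vertices for uniform resampling before curvature.
DEFAULT_RESAMPLE_N = 512
#: Default curvature-profile smoothing, in pixels of arc length.
DEFAULT_PROFILE_SMOOTH_PX = 3.0
#: Default number of harmonics for the elliptic Fourier descriptor.
DEFAULT_EFD_ORDER = 10


def default_curvature_bins(n_bins: int = 32, kappa_max: float = 0.5) -> np.ndarray:
    """Bin edges for curvature histograms: ``n_bins`` over [-kappa_max, kappa_max] rad/px."""
    return np.linspace(-kappa_max, kappa_max, n_bins + 1)


def log_curvature_bins(kappa_min: float = 0.012, kappa_max: float = 0.35,
                       n_per_side: int = 10) -> np.ndarray:
    """Sign-symmetric log-spaced bin edges: geometric ladder over
    [kappa_min, kappa_max] mirrored about zero, with one central bin
    covering the effectively-straight band (-kappa_min, kappa_min).

    Log spacing matches the multiplicative structure of contour curvature
    (a feature twice as curved is "one step" away at every scale), so class
    differences occupy a constant number of bins across the whole range.
    """
    if not 0 < kappa_min < kappa_max:
        raise ValueError("need 0 < kappa_min < kappa_max")
    if n_per_side < 1:
        raise ValueError("n_per_side must be >= 1")
    pos = np.geomspace(kappa_min, kappa_max, n_per_side + 1)
    return np.concatenate([-pos[::-1], pos])


@dataclass(frozen=True)
class CurvatureProfile:
    """Signed curvature along a uniformly resampled closed contour.

    ``kappa[i]`` is the turning angle at vertex ``i`` divided by the mean of
    the two adjacent segment lengths (radians / pixel; positive = convex
    under the counterclockwise convention).  ``arclength[i]`` is the
    cumulative arc length at vertex ``i`` and ``ds[i]`` the arc length
    attributed to that vertex (used as histogram weight).
    """

    kappa: np.ndarray
    arclength: np.ndarray
    ds: np.ndarray

    @property
    def total_length(self) -> float:
        return float(self.ds.sum())


@dataclass(frozen=True)
class ShapeDescriptor:
    """Normalized elliptic Fourier coefficients of a closed contour.

    ``harmonics`` has shape ``(m, 4)`` with columns ``(a_k, b_k, c_k, d_k)``
    for harmonic ``k = 1..m`` (x = col driven by a/b, y = row by c/d).
    Translation is always removed and scale normalized so the first
    harmonic has unit Frobenius norm; the contour start point is
    phase-normalized so descriptors do not depend on where tracing began.
    Rotation normalization is applied iff ``rotation_normalized``.
    """

    harmonics: np.ndarray
    rotation_normalized: bool = False

    @property
    def order(self) -> int:
        return self.harmonics.shape[0]


@dataclass(frozen=True)
class ManipulationReport:
    """Quantifies what a contour manipulation preserved vs destroyed.

    ``global_distance`` — descriptor-space distance between the original
    and manipulated shapes (elliptic Fourier, L2).  ``local_distance`` —
    symmetric chi-square distance between curvature histograms.
    ``area_ratio`` — manipulated foreground area / original area.
    """

    global_distance: float
    local_distance: float
    area_ratio: float
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.global_distance < 0 or self.local_distance < 0:
            raise ValueError("distances must be nonnegative")
        if not self.area_ratio > 0:
            raise ValueError("area_ratio must be positive")


# ---------------------------------------------------------------------------
# basic polyline helpers


def _as_contour(vertices) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise ValueError("contour must be an (n>=3, 2) array of (row, col)")
    if np.allclose(v[0], v[-1]):
        v = v[:-1]
    return v


def signed_area(vertices) -> float:
    """Shoelace signed area with x = col, y = -row (CCW positive on screen)."""
    v = _as_contour(vertices)
    x = v[:, 1]
    y = -v[:, 0]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def contour_length(vertices) -> float:
    v = _as_contour(vertices)
    d = np.diff(np.vstack([v, v[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _ensure_ccw(v: np.ndarray) -> np.ndarray:
    return v if signed_area(v) > 0 else v[::-1]


def resample_arclength(vertices, n: int) -> np.ndarray:
    """Resample a closed contour to ``n`` vertices at uniform arc-length spacing.

    The total polyline length is preserved (piecewise-linear interpolation
    along the original edges); the start point is kept.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    v = _as_contour(vertices)
    vc = np.vstack([v, v[:1]])
    seg = np.hypot(*np.diff(vc, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise ValueError("degenerate contour with zero length")
    t = np.linspace(0.0, s[-1], n, endpoint=False)
    return np.stack([np.interp(t, s, vc[:, k]) for k in range(2)], axis=1)


def smooth_contour(vertices, sigma_px: float, spacing: float = 0.5) -> np.ndarray:
    """Gaussian-smooth vertex positions along arc length (periodic).

    The contour is first resampled at ~``spacing`` px so that ``sigma_px``
    is a true arc-length scale regardless of vertex density.
    """
    v = _as_contour(vertices)
    if sigma_px <= 0:
        return v
    length = contour_length(v)
    n = max(64, int(np.ceil(length / spacing)))
    r = resample_arclength(v, n)
    return gaussian_filter1d(r, sigma_px / (length / n), axis=0, mode="wrap")


# ---------------------------------------------------------------------------
# extraction / rasterization


def _validate_mask(mask) -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError("mask must be 2D")
    vals = np.unique(m)
    if not np.all(np.isin(vals, [0, 1])):
        raise ValueError("mask values must be in {0, 1}")
    if not m.any():
        raise ValueError("no foreground: mask has no foreground pixels")
    return m.astype(np.uint8)


def largest_component(mask) -> np.ndarray:
    """Largest 8-connected foreground component of a binary mask."""
    m = _validate_mask(mask)
    lab = _measure.label(m, connectivity=2)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return (lab == counts.argmax()).astype(np.uint8)


def extract_contour(mask, smooth_px: float = DEFAULT_SMOOTH_PX) -> np.ndarray:
    """Bounding contour of the largest 8-connected foreground component.

    Marching squares at the 0.5 level gives a subpixel closed polyline; a
    light arc-length Gaussian (``smooth_px``) then removes the raster
    staircase, whose excess length would otherwise bias arc-length and
    curvature measurements.  Returns a CCW ``(n, 2)`` array, first vertex
    not repeated.  Pass ``smooth_px=0`` for the raw marching-squares
    polyline.
    """
    comp = largest_component(mask)
    padded = np.pad(comp, 1).astype(float)
    contours = _measure.find_contours(padded, 0.5)
    if not contours:  # pragma: no cover - nonempty mask always yields one
        raise ValueError("no contour found")
    c = max(contours, key=lambda a: abs(signed_area(a)) if len(a) >= 3 else 0.0)
    v = _as_contour(c) - 1.0  # undo padding offset
    if smooth_px > 0 and contour_length(v) > 8 * smooth_px:
        v = smooth_contour(v, smooth_px)
    return _ensure_ccw(v)


def rasterize(vertices, height: int, width: int) -> np.ndarray:
    """Fill the interior of a closed contour on an ``height x width`` canvas.

    The round trip ``extract_contour(rasterize(c))`` preserves the shape up
    to raster resolution (elliptic-Fourier distance < 1e-2 at order 10 for
    smooth contours of typical stimulus size).
    """
    v = _as_contour(vertices)
    if v[:, 0].min() < -0.5 or v[:, 1].min() < -0.5 or v[:, 0].max() > height - 0.5 or v[:, 1].max() > width - 0.5:
        raise ValueError("contour exceeds canvas")
    rr, cc = _draw.polygon(v[:, 0], v[:, 1], shape=(height, width))
    mask = np.zeros((height, width), dtype=np.uint8)
    mask[rr, cc] = 1
    return mask


# ---------------------------------------------------------------------------
# curvature


def curvature_profile(
    vertices,
    profile_smooth_px: float = DEFAULT_PROFILE_SMOOTH_PX,
) -> CurvatureProfile:
    """Signed turning-angle curvature along a uniformly resampled contour.

    Expects uniform vertex spacing (see :func:`resample_arclength`); raises
    if spacings vary widely.  Collinear duplicate vertices are dropped with
    a warning.  ``profile_smooth_px`` is a periodic Gaussian in *arc
    length* applied to the curvature sequence to suppress residual raster
    noise — fixed in pixels so the smoothing scale does not depend on the
    resampling density.  With ``profile_smooth_px=0`` the weighted sum
    ``sum(kappa * ds)`` equals the total turning angle exactly (2*pi for a
    simple CCW contour); smoothing preserves it approximately (the Gaussian
    conserves ``sum(kappa)`` while ``ds`` varies slightly).
    """
    v = _as_contour(vertices)
    dseg = np.diff(np.vstack([v, v[:1]]), axis=0)
    seg = np.hypot(dseg[:, 0], dseg[:, 1])
    if (seg == 0).any():
        warnings.warn("removing duplicate vertices", stacklevel=2)
        v = v[np.concatenate([[True], seg[:-1] > 0])]
        dseg = np.diff(np.vstack([v, v[:1]]), axis=0)
        seg = np.hypot(dseg[:, 0], dseg[:, 1])
    # chord lengths shrink slightly where corners fall between samples, so
    # allow modest spread before declaring the contour non-uniform
    if seg.std() > 0.10 * seg.mean():
        raise ValueError("contour must be uniformly resampled (see resample_arclength)")
    # tangent angle in the (x=col, y=-row) frame so CCW turns are positive
    ang = np.arctan2(-dseg[:, 0], dseg[:, 1])
    turn = np.diff(np.concatenate([ang, ang[:1]]))
    turn = (turn + np.pi) % (2.0 * np.pi) - np.pi
    ds = 0.5 * (seg + np.roll(seg, -1))  # arc length attributed to each vertex
    kappa = turn / ds
    if profile_smooth_px > 0:
        kappa = gaussian_filter1d(kappa, profile_smooth_px / seg.mean(), mode="wrap")
    arclength = np.concatenate([[0.0], np.cumsum(seg[:-1])])
    return CurvatureProfile(kappa=kappa, arclength=arclength, ds=ds)


def curvature_histogram(
    profile: CurvatureProfile,
    bins: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Arc-length-weighted curvature histogram, normalized to sum to 1.

    Curvatures outside the bin range are clipped into the end bins (with a
    warning).  ``weights`` multiplies the per-vertex arc lengths — pass
    zeros to exclude vertices (e.g. artificial cut edges) from the
    statistic.
    """
    if bins is None:
        bins = default_curvature_bins()
    bins = np.asarray(bins, dtype=float)
    if bins.ndim != 1 or len(bins) < 2 or not np.all(np.diff(bins) > 0):
        raise ValueError("bins must be a strictly increasing 1D edge list")
    k = profile.kappa
    if k.min() < bins[0] or k.max() > bins[-1]:
        warnings.warn("curvature values outside bin range clipped to end bins", stacklevel=2)
    eps = 1e-12 * max(1.0, abs(bins[-1]))
    k = np.clip(k, bins[0] + eps, bins[-1] - eps)
    w = profile.ds if weights is None else profile.ds * np.asarray(weights, dtype=float)
    hist, _ = np.histogram(k, bins=bins, weights=w)
    total = hist.sum()
    if total <= 0:
        raise ValueError("histogram has zero total weight")
    return hist / total


def local_feature_distance(h1, h2) -> float:
    """Symmetric chi-square distance between two normalized histograms.

    ``0.5 * sum (h1-h2)^2 / (h1+h2)``; zero iff identical, bounded above
    by 1 for probability histograms (value 1 at disjoint support).
    """
    a = np.asarray(h1, dtype=float)
    b = np.asarray(h2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("histograms must share bin edges (mismatched length)")
    denom = a + b
    m = denom > 0
    return 0.5 * float(np.sum((a[m] - b[m]) ** 2 / denom[m]))


# ---------------------------------------------------------------------------
# elliptic Fourier descriptors


def _efd_coefficients(vertices, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Raw Kuhl-Giardina coefficients (m, 4) + DC term, x = col, y = -row."""
    v = _as_contour(vertices)
    vc = np.vstack([v, v[:1]])
    dxy = np.diff(np.column_stack([vc[:, 1], -vc[:, 0]]), axis=0)  # (x, y) steps
    dt = np.hypot(dxy[:, 0], dxy[:, 1])
    keep = dt > 0
    dxy, dt = dxy[keep], dt[keep]
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    phi = 2.0 * np.pi * t / T
    coeffs = np.empty((m, 4))
    for k in range(1, m + 1):
        const = T / (2.0 * k * k * np.pi * np.pi)
        dcos = np.cos(k * phi[1:]) - np.cos(k * phi[:-1])
        dsin = np.sin(k * phi[1:]) - np.sin(k * phi[:-1])
        coeffs[k - 1, 0] = const * np.sum(dxy[:, 0] / dt * dcos)
        coeffs[k - 1, 1] = const * np.sum(dxy[:, 0] / dt * dsin)
        coeffs[k - 1, 2] = const * np.sum(dxy[:, 1] / dt * dcos)
        coeffs[k - 1, 3] = const * np.sum(dxy[:, 1] / dt * dsin)
    return coeffs, t


def _rotate_phase(coeffs: np.ndarray, theta: float) -> np.ndarray:
    """Shift the contour start point by phase theta (per-harmonic rotation)."""
    out = np.empty_like(coeffs)
    for k in range(1, coeffs.shape[0] + 1):
        c, s = np.cos(k * theta), np.sin(k * theta)
        rot = np.array([[c, -s], [s, c]])
        out[k - 1] = (coeffs[k - 1].reshape(2, 2) @ rot).ravel()
    return out


def _rotate_spatial(coeffs: np.ndarray, psi: float) -> np.ndarray:
    """Rotate the curve in the plane by -psi."""
    c, s = np.cos(psi), np.sin(psi)
    rot = np.array([[c, s], [-s, c]])
    out = np.empty_like(coeffs)
    for k in range(coeffs.shape[0]):
        out[k] = (rot @ coeffs[k].reshape(2, 2)).ravel()
    return out


def elliptic_fourier(
    vertices,
    m: int = DEFAULT_EFD_ORDER,
    normalize_rotation: bool = False,
) -> ShapeDescriptor:
    """Normalized elliptic Fourier descriptor of a closed contour.

    Translation is removed by construction (the DC term is dropped).  The
    start point is normalized to the first semi-major axis, with the
    residual two-fold ambiguity resolved by sign conventions, so that
    descriptors of the same curve traced from different start points agree.
    Scale is normalized to unit first-harmonic Frobenius norm.  With
    ``normalize_rotation`` the curve is additionally rotated so its first
    ellipse's major axis aligns with the x axis (descriptors then agree
    across rigid rotations of the shape).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    v = _as_contour(vertices)
    if m > len(v) // 2:
        raise ValueError("m too large for contour vertex count (need m <= n/2)")
    v = _ensure_ccw(v)
    coeffs, _ = _efd_coefficients(v, m)

    a1, b1, c1, d1 = coeffs[0]
    # start-point phase to the first-ellipse major axis (Kuhl & Giardina)
    theta = 0.5 * np.arctan2(2.0 * (a1 * b1 + c1 * d1), a1 * a1 + c1 * c1 - b1 * b1 - d1 * d1)
    coeffs = _rotate_phase(coeffs, theta)
    # theta is defined mod pi: pick the half-period putting the larger lobe first
    if np.hypot(coeffs[0, 0], coeffs[0, 2]) < np.hypot(coeffs[0, 1], coeffs[0, 3]):
        coeffs = _rotate_phase(coeffs, np.pi / 2)
    if normalize_rotation:
        psi = np.arctan2(coeffs[0, 2], coeffs[0, 0])
        coeffs = _rotate_spatial(coeffs, psi)
        if coeffs[0, 0] < 0:  # residual pi ambiguity
            coeffs = _rotate_spatial(coeffs, np.pi)
    if np.hypot(coeffs[0, 0], coeffs[0, 2]) > 0 and coeffs[0, 0] + coeffs[0, 2] < 0:
        # fix the remaining start-point sign so mirrored phases don't flip
        coeffs = _rotate_phase(coeffs, np.pi)
    scale = np.linalg.norm(coeffs[0])
    if scale <= 0:
        raise ValueError("degenerate contour: vanishing first harmonic")
    return ShapeDescriptor(harmonics=coeffs / scale, rotation_normalized=normalize_rotation)


def gauge_flip(harmonics: np.ndarray) -> np.ndarray:
    """The residual half-period start-point gauge of a normalized descriptor.

    Start-point normalization fixes the tracing origin only up to a
    half-period shift, which negates every odd harmonic.  Descriptors of
    the same curve may land in either gauge; comparisons are therefore
    taken on the quotient (see :func:`global_shape_distance`).
    """
    out = harmonics.copy()
    out[::2] = -out[::2]  # harmonics k = 1, 3, 5, ... (0-indexed even rows)
    return out


def global_shape_distance(d1: ShapeDescriptor, d2: ShapeDescriptor) -> float:
    """L2 distance between matched normalized harmonics.

    Computed on the quotient over the residual start-point gauge (the
    minimum over the half-period flip), so equal curves traced from
    different origins are at distance 0.  Symmetric, satisfies the
    triangle inequality on the quotient.
    """
    if d1.order != d2.order:
        raise ValueError("descriptors must have the same number of harmonics")
    if d1.rotation_normalized != d2.rotation_normalized:
        raise ValueError("descriptors must share normalization flags")
    plain = float(np.linalg.norm(d1.harmonics - d2.harmonics))
    flipped = float(np.linalg.norm(gauge_flip(d1.harmonics) - d2.harmonics))
    return min(plain, flipped)


# ---------------------------------------------------------------------------
# convenience pipelines


def mask_curvature_histogram(
    mask,
    bins: np.ndarray | None = None,
    n: int = DEFAULT_RESAMPLE_N,
    all_components: bool = False,
    min_component_area: int = 16,
    exclude_segments: list | None = None,
    exclude_tol: float = 2.0,
    spike_thresh: float = 0.0,
    spike_win_px: float = 5.0,
    allow_empty: bool = False,
) -> np.ndarray:
    """Curvature histogram of a mask's bounding contour(s).

    With ``all_components`` the histogram pools arc-length-weighted
    curvature over every foreground component of at least
    ``min_component_area`` pixels — the "bag of local contour features"
    view, indifferent to how parts are arranged.  ``exclude_segments`` is a
    list of ``((r0, c0), (r1, c1))`` segments; vertices within
    ``exclude_tol`` px of any segment get zero weight (used to discount
    artificial straight cut edges).

    With ``spike_thresh > 0``, arc within ``spike_win_px`` of any vertex
    whose *unsmoothed* curvature exceeds the threshold also gets zero
    weight.  Genuine smooth contour never reaches such raw curvature, so
    this discounts isolated corner-like singularities (e.g. the junctions
    a straight cut leaves behind) without looking at anything but the mask.
    ``allow_empty`` returns an all-zero histogram instead of raising when
    every vertex is excluded or out of range.
    """
    if bins is None:
        bins = default_curvature_bins()
    m = _validate_mask(mask)
    if all_components:
        lab = _measure.label(m, connectivity=2)
        comps = [
            (lab == i).astype(np.uint8)
            for i in range(1, lab.max() + 1)
            if (lab == i).sum() >= min_component_area
        ]
        if not comps:
            comps = [largest_component(m)]
    else:
        comps = [largest_component(m)]
    total = np.zeros(len(bins) - 1)
    for comp in comps:
        v = extract_contour(comp)
        length = contour_length(v)
        # ~1 px spacing for every component, so curvature statistics are
        # measured at the same arc resolution regardless of piece size
        r = resample_arclength(v, int(np.clip(round(length), 64, 4096)))
        prof = curvature_profile(r)
        ww = prof.ds.copy()
        if exclude_segments:
            ww *= _segment_exclusion_weights(r, exclude_segments, exclude_tol)
        if spike_thresh > 0:
            raw = curvature_profile(r, profile_smooth_px=0.0)
            n = len(ww)
            win = max(0, int(round(spike_win_px)))
            for s_idx in np.flatnonzero(np.abs(raw.kappa) > spike_thresh):
                ww[np.arange(s_idx - win, s_idx + win + 1) % n] = 0.0
        eps = 1e-12
        k = np.clip(prof.kappa, bins[0] + eps, bins[-1] - eps)
        h, _ = np.histogram(k, bins=bins, weights=ww)
        total += h
    s = total.sum()
    if s <= 0:
        if allow_empty:
            return total
        raise ValueError("empty pooled histogram")
    return total / s


def _segment_exclusion_weights(vertices: np.ndarray, segments, tol: float) -> np.ndarray:
    """0/1 weights: 0 where a vertex lies within tol px of any segment."""
    v = np.asarray(vertices, dtype=float)
    keep = np.ones(len(v), dtype=float)
    for (p0, p1) in segments:
        p0 = np.asarray(p0, dtype=float)
        p1 = np.asarray(p1, dtype=float)
        d = p1 - p0
        L2 = float(d @ d)
        if L2 == 0:
            dist = np.hypot(*(v - p0).T)
        else:
            t = np.clip((v - p0) @ d / L2, 0.0, 1.0)
            proj = p0 + t[:, None] * d
            dist = np.hypot(*(v - proj).T)
        keep[dist <= tol] = 0.0
    return keep
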