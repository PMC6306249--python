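"""Seeded synthetic shape classes, exemplar masks, and procedural textures.

The generator emulates the structure of the study's stimulus set: single
objects on uniform backgrounds, in two superordinate groups — smooth
"animal-like" blobs (radial Fourier outlines) and straight-edged
"artifact-like" polygons — with class-level templates and exemplar-level
jitter, so that classifiers can be trained and probed without any
downloaded images.

A blob class is a radius function around a base radius ``r0``::

    r(theta) = r0 * (1 + sum_k a_k cos(k*theta + phi_k)),   k = 2..8

with ``sum |a_k| < 0.9`` guaranteeing ``r > 0`` and hence a simple closed
outline.  Harmonics are capped at k = 8 so the blob's own structure stays
well below the spatial frequency of the serration manipulation, keeping
the local/global contrast interpretable.  Polygon classes are jittered
radial vertex templates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import draw as _draw

__all__ = [
    "ShapeClassSpec",
    "TextureSpec",
    "Catalog",
    "gen_shape_class",
    "sample_mask",
    "gen_texture",
    "build_catalog",
]

_MAX_AMP_SUM = 0.9
_BLOB_HARMONICS = range(2, 9)


@dataclass(frozen=True)
class ShapeClassSpec:
    """Template for one shape category.

    ``kind`` is "blob" (radial Fourier outline) or "polygon" (radial vertex
    template).  ``amplitudes``/``phases`` are the blob harmonics a_k, phi_k
    for k = 2..8; ``template_radii``/``template_angles`` the polygon
    spokes.  Jitter magnitudes control exemplar variation.
    """

    name: str
    kind: str
    r0: float = 60.0
    amplitudes: tuple = ()
    phases: tuple = ()
    template_radii: tuple = ()
    template_angles: tuple = ()
    amp_jitter: float = 0.05      # relative jitter on blob amplitudes
    phase_jitter: float = 0.05    # radians, blob phases
    radius_jitter: float = 0.02   # relative jitter on r0 / polygon radii
    def __post_init__(self):
        if self.kind not in ("blob", "polygon"):
            raise ValueError("kind must be 'blob' or 'polygon'")
        if self.kind == "blob" and sum(abs(a) for a in self.amplitudes) >= _MAX_AMP_SUM:
            raise ValueError("sum |a_k| must be < 0.9 to keep r(theta) > 0")


@dataclass(frozen=True)
class TextureSpec:
    """Procedural texture: grating, checkerboard or dots, two colors, seeded."""

    kind: str
    period: float = 16.0
    angle: float = 0.0
    color_a: tuple = (0, 0, 0)
    color_b: tuple = (255, 255, 255)
    dot_radius: float = 4.0
    density: float = 0.01
    seed: int = 0
    constant: bool = False

    def __post_init__(self):
        if self.kind not in ("grating", "checkerboard", "dots"):
            raise ValueError("kind must be grating|checkerboard|dots")
        if not self.constant and self.color_a == self.color_b:
            raise ValueError("non-constant texture needs two distinct colors")


@dataclass(frozen=True)
class Catalog:
    """Per-class exemplar masks with disjoint train/test splits, fully seeded."""

    vocabulary: tuple
    train: dict = field(repr=False, default_factory=dict)
    test: dict = field(repr=False, default_factory=dict)
    specs: dict = field(repr=False, default_factory=dict)
    seed: int = 0


def gen_shape_class(seed: int, kind: str, name: str | None = None, r0: float = 60.0,
                    dominant: tuple | None = None, dominant_amp: float | None = None,
                    n_vertices: int | None = None,
                    **jitter) -> ShapeClassSpec:
    """Draw a deterministic class template for the given kind and seed.

    ``dominant`` (blobs) picks which two harmonics carry the class's
    silhouette and ``dominant_amp`` the curvature-deviation pair they
    contribute (see the in-line note below); ``n_vertices`` (polygons)
    fixes the vertex count.  All default to seeded random choices;
    :func:`build_catalog` cycles them so categories are structurally
    distinct, the way real object categories differ in part structure and
    not just in metric detail.
    """
    rng = np.random.default_rng(seed)
    name = name or f"{kind}_{seed}"
    if kind == "blob":
        # Two dominant harmonics give each class a distinctive silhouette.
        # Class identity is pinned by the *curvature deviation* each dominant
        # contributes, d_k = a_k (k^2 - 1), because the local curvature of
        # r = r0 (1 + a cos k0) is kappa ~ (1 + sum d_k cos) / r0: classes
        # with equal deviation sets are near-twins to any curvature-based
        # observer even when their (k, a) decompositions differ.  Minor
        # harmonics add only sub-dominant idiosyncrasy (d < 0.4).
        ks = np.array(_BLOB_HARMONICS)
        amps = rng.uniform(0.1, 0.4, size=len(ks)) / (ks ** 2 - 1)
        if dominant is None:
            dominant = tuple(rng.choice(len(ks), size=2, replace=False))
        if dominant_amp is None:
            dominant_amp = tuple(rng.uniform(2.0, 8.0, size=2))
        dev = np.asarray(dominant_amp, dtype=float) * rng.uniform(0.95, 1.05, size=2)
        amps[list(dominant)] = dev / (ks[list(dominant)] ** 2 - 1)
        total = amps.sum()
        if total >= _MAX_AMP_SUM * 0.75:  # stay clear of the positivity bound
            amps *= (_MAX_AMP_SUM * 0.75) / total
        phases = rng.uniform(0, 2 * np.pi, size=len(amps))
        return ShapeClassSpec(name=name, kind="blob", r0=r0,
                              amplitudes=tuple(amps), phases=tuple(phases), **jitter)
    if kind == "polygon":
        n_vert = int(n_vertices) if n_vertices else int(rng.integers(3, 10))
        angles = np.sort(rng.uniform(0, 2 * np.pi, size=n_vert))
        # enforce minimum angular gap so edges stay resolvable
        while np.min(np.diff(np.concatenate([angles, [angles[0] + 2 * np.pi]]))) < 0.35:
            angles = np.sort(rng.uniform(0, 2 * np.pi, size=n_vert))
        radii = rng.uniform(0.55, 1.0, size=n_vert) * r0
        return ShapeClassSpec(name=name, kind="polygon", r0=r0,
                              template_radii=tuple(radii), template_angles=tuple(angles),
                              **jitter)
    raise ValueError("kind must be 'blob' or 'polygon'")


def _blob_polyline(spec: ShapeClassSpec, rng: np.random.Generator, center, n_theta=720):
    amps = np.array(spec.amplitudes) * (1 + rng.normal(0, spec.amp_jitter, len(spec.amplitudes)))
    amps = np.clip(amps, 0, None)
    total = np.abs(amps).sum()
    if total >= _MAX_AMP_SUM:
        amps *= (_MAX_AMP_SUM - 1e-3) / total
    phases = np.array(spec.phases) + rng.normal(0, spec.phase_jitter, len(spec.phases))
    r0 = spec.r0 * (1 + rng.normal(0, spec.radius_jitter))
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    r = r0 * (1 + sum(a * np.cos(k * theta + p)
                      for a, p, k in zip(amps, phases, _BLOB_HARMONICS)))
    rows = center[0] - r * np.sin(theta)
    cols = center[1] + r * np.cos(theta)
    return rows, cols, r.max()


def _polygon_polyline(spec: ShapeClassSpec, rng: np.random.Generator, center):
    radii = np.array(spec.template_radii) * (1 + rng.normal(0, spec.radius_jitter,
                                                            len(spec.template_radii)))
    angles = np.array(spec.template_angles)
    rows = center[0] - radii * np.sin(angles)
    cols = center[1] + radii * np.cos(angles)
    return rows, cols, radii.max()


def sample_mask(spec: ShapeClassSpec, seed: int, canvas: tuple = (224, 224)) -> np.ndarray:
    """Rasterize one jittered exemplar of a shape class onto ``canvas``.

    Deterministic given ``(spec, seed)``.  Raises if the canvas cannot hold
    the worst-case extent of the class.
    """
    h, w = canvas
    rng = np.random.default_rng(seed)
    center = (h / 2.0, w / 2.0)
    if spec.kind == "blob":
        max_extent = spec.r0 * (1 + sum(abs(a) for a in spec.amplitudes)) * 1.1
    else:
        max_extent = max(spec.template_radii) * 1.1
    if max_extent > min(h, w) / 2.0:
        raise ValueError("canvas too small for this shape class")
    if spec.kind == "blob":
        rows, cols, _ = _blob_polyline(spec, rng, center)
    else:
        rows, cols, _ = _polygon_polyline(spec, rng, center)
    rr, cc = _draw.polygon(rows, cols, shape=canvas)
    mask = np.zeros(canvas, dtype=np.uint8)
    mask[rr, cc] = 1
    return mask


def gen_texture(spec: TextureSpec, size: tuple) -> np.ndarray:
    """Render an ``(H, W, 3)`` uint8 procedural texture, deterministic in spec.seed."""
    h, w = size
    if h <= 0 or w <= 0:
        raise ValueError("size must be positive")
    a = np.array(spec.color_a, dtype=np.uint8)
    b = np.array(spec.color_b, dtype=np.uint8)
    if spec.constant:
        return np.tile(a, (h, w, 1))
    yy, xx = np.mgrid[0:h, 0:w]
    if spec.kind == "grating":
        u = xx * np.cos(spec.angle) + yy * np.sin(spec.angle)
        field = ((u // (spec.period / 2)).astype(int) % 2).astype(bool)
    elif spec.kind == "checkerboard":
        field = (((yy // spec.period).astype(int) + (xx // spec.period).astype(int)) % 2).astype(bool)
    else:  # dots
        rng = np.random.default_rng(spec.seed)
        n = max(1, int(spec.density * h * w))
        centers = rng.uniform([0, 0], [h, w], size=(n, 2))
        field = np.zeros((h, w), dtype=bool)
        for (cy, cx) in centers:
            rr, cc = _draw.disk((cy, cx), spec.dot_radius, shape=(h, w))
            field[rr, cc] = True
    img = np.where(field[..., None], a[None, None], b[None, None])
    return img.astype(np.uint8)


def build_catalog(C: int, E: int, seed: int, blob_fraction: float = 0.5,
                  canvas: tuple = (224, 224)) -> Catalog:
    """C classes x E exemplars, 50/50 train/test split, one top-level seed.

    The first ``round(C * blob_fraction)`` classes are blobs ("animal-like"
    group), the rest polygons ("artifact-like").  With ``C=40, E=20`` this
    mirrors the 20 + 20 two-group structure of the study's stimulus set.
    """
    if C < 2 or E < 2:
        raise ValueError("need C >= 2 classes and E >= 2 exemplars")
    rng = np.random.default_rng(seed)
    n_blob = int(round(C * blob_fraction))
    # cycle structural templates so categories differ in kind, not just metric
    # Each blob class is a (harmonic pair, curvature-deviation pair) combo.
    # Deviation levels lie on a ~1.58x geometric ladder and the ten pairs are
    # chosen so that any two classes sharing a level differ by at least two
    # ladder steps in the other — a curvature-based observer then never has
    # to resolve a single sub-bin difference to tell two classes apart.  The
    # lower deviation rides the lower harmonic to keep amplitudes in range.
    lv = (1.2, 1.9, 3.0, 4.7, 7.5, 11.9, 18.8)
    blob_dev_pairs = [(lv[0], lv[1]), (lv[0], lv[3]), (lv[0], lv[5]),
                      (lv[1], lv[2]), (lv[1], lv[4]), (lv[1], lv[6]),
                      (lv[2], lv[3]), (lv[2], lv[5]), (lv[3], lv[4]),
                      (lv[5], lv[6])]
    # harmonic indices are k - 2 (harmonics run k = 2..8); chosen per class
    # so a_k = d / (k^2 - 1) stays comfortably below the positivity bound
    blob_dominants = [(1, 2), (1, 3), (1, 5), (2, 3), (1, 4), (2, 6), (2, 4),
                      (3, 5), (3, 4), (5, 6)]
    poly_sides = [3, 4, 5, 6, 7, 8, 9]
    specs: dict[str, ShapeClassSpec] = {}
    train: dict[str, list] = {}
    test: dict[str, list] = {}
    for i in range(C):
        kind = "blob" if i < n_blob else "polygon"
        class_seed = int(rng.integers(0, 2**31 - 1))
        name = f"{kind}{i:02d}"
        if kind == "blob":
            spec = gen_shape_class(class_seed, kind, name=name,
                                   dominant=blob_dominants[i % len(blob_dominants)],
                                   dominant_amp=blob_dev_pairs[i % len(blob_dev_pairs)])
        else:
            j = i - n_blob
            spec = gen_shape_class(class_seed, kind, name=name,
                                   n_vertices=poly_sides[j % len(poly_sides)])
        specs[name] = spec
        masks = [sample_mask(spec, int(rng.integers(0, 2**31 - 1)), canvas)
                 for _ in range(E)]
        half = E // 2
        train[name] = masks[:half]
        test[name] = masks[half:]
    return Catalog(vocabulary=tuple(specs), train=train, test=test, specs=specs, seed=seed)
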