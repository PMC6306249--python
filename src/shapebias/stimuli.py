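"""Stimulus construction: silhouettes, outlines, texture chimeras, and the
two shape manipulations that dissociate local contour features from global
shape.

* ``part_scramble`` cuts a figure into pieces along straight chords and
  rigidly rearranges them: local edge curvature is preserved (up to the
  artificial cut edges) while the global configuration is destroyed.
* ``serrate`` adds a high-frequency sawtooth displacement along the
  bounding contour: local edges are destroyed while the global
  configuration survives.

Each manipulation returns a :class:`~shapebias.geometry.ManipulationReport`
quantifying the dissociation (elliptic-Fourier distance for global shape,
curvature-histogram chi-square for local features, plus area conservation).

Renderers place the mask centered and isotropically scaled to occupy 80%
of the shorter canvas side (224x224 RGB default, the common classifier
input size), and never touch pixels outside their specified regions.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage import measure as _measure
from skimage import morphology as _morph
from skimage.transform import resize as _resize

from . import geometry as G

__all__ = [
    "Colorway",
    "StimulusRecord",
    "StimulusImage",
    "BLACK_ON_WHITE",
    "WHITE_ON_BLACK",
    "RED_ON_WHITE",
    "place_mask",
    "render_silhouette",
    "render_outline",
    "render_texture_chimera",
    "part_scramble",
    "serrate",
    "manipulation_report",
    "save_stimulus",
    "load_stimulus",
    "write_manifest",
]

DEFAULT_CANVAS = (224, 224)
DEFAULT_FILL_FRACTION = 0.8


@dataclass(frozen=True)
class Colorway:
    """Foreground/background RGB pair for silhouette rendering."""

    fg: tuple
    bg: tuple

    def __post_init__(self):
        if tuple(self.fg) == tuple(self.bg):
            raise ValueError("foreground and background colors must differ")


BLACK_ON_WHITE = Colorway(fg=(0, 0, 0), bg=(255, 255, 255))
WHITE_ON_BLACK = Colorway(fg=(255, 255, 255), bg=(0, 0, 0))
RED_ON_WHITE = Colorway(fg=(255, 0, 0), bg=(255, 255, 255))


@dataclass(frozen=True)
class StimulusRecord:
    """Provenance of one generated stimulus: enough to reconstruct it."""

    shape_label: str
    manipulation: str  # silhouette | outline | chimera | part_scramble | serrate
    texture_label: str | None = None
    colorway: Colorway = BLACK_ON_WHITE
    params: dict = field(default_factory=dict)
    seed: int | None = None
    item_id: str | None = None

    def __post_init__(self):
        if (self.manipulation == "chimera") != (self.texture_label is not None):
            raise ValueError("texture_label present iff manipulation == 'chimera'")
        if self.manipulation == "part_scramble" and self.seed is None:
            raise ValueError("stochastic manipulation requires a seed")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["colorway"] = {"fg": list(self.colorway.fg), "bg": list(self.colorway.bg)}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusRecord":
        d = dict(d)
        cw = d.pop("colorway")
        return cls(colorway=Colorway(fg=tuple(cw["fg"]), bg=tuple(cw["bg"])), **d)


@dataclass(frozen=True)
class StimulusImage:
    """An RGB raster together with the record that produced it."""

    pixels: np.ndarray
    record: StimulusRecord


# ---------------------------------------------------------------------------
# placement and renderers


def place_mask(mask, out_size: tuple = DEFAULT_CANVAS,
               fill_fraction: float = DEFAULT_FILL_FRACTION) -> np.ndarray:
    """Center the mask and scale it isotropically to ``fill_fraction`` of
    the shorter canvas side (nearest-neighbour, so the result stays binary)."""
    m = np.asarray(mask)
    if not m.any():
        raise ValueError("no foreground: empty mask")
    rows = np.any(m, axis=1)
    cols = np.any(m, axis=0)
    r0, r1 = np.where(rows)[0][[0, -1]]
    c0, c1 = np.where(cols)[0][[0, -1]]
    crop = m[r0:r1 + 1, c0:c1 + 1]
    H, W = out_size
    target = fill_fraction * min(H, W)
    scale = target / max(crop.shape)
    new_shape = (max(1, int(round(crop.shape[0] * scale))),
                 max(1, int(round(crop.shape[1] * scale))))
    scaled = _resize(crop.astype(float), new_shape, order=0,
                     anti_aliasing=False, preserve_range=True) > 0.5
    out = np.zeros(out_size, dtype=np.uint8)
    off_r = (H - new_shape[0]) // 2
    off_c = (W - new_shape[1]) // 2
    out[off_r:off_r + new_shape[0], off_c:off_c + new_shape[1]] = scaled
    return out


def _blank(out_size, color) -> np.ndarray:
    img = np.empty((*out_size, 3), dtype=np.uint8)
    img[:] = np.asarray(color, dtype=np.uint8)
    return img


def render_silhouette(mask, colorway: Colorway = BLACK_ON_WHITE,
                      out_size: tuple = DEFAULT_CANVAS,
                      record: StimulusRecord | None = None) -> StimulusImage:
    """Uniformly filled figure on a uniform background: shape is conveyed
    only by the bounding contour."""
    placed = place_mask(mask, out_size)
    img = _blank(out_size, colorway.bg)
    img[placed.astype(bool)] = np.asarray(colorway.fg, dtype=np.uint8)
    rec = record or StimulusRecord(shape_label="", manipulation="silhouette",
                                   colorway=colorway)
    return StimulusImage(pixels=img, record=rec)


def render_outline(mask, stroke_px: int = 2, out_size: tuple = DEFAULT_CANVAS,
                   record: StimulusRecord | None = None) -> StimulusImage:
    """Black stroke centered on the bounding contour; interior and exterior
    share the same uniform white, so contrast exists only at the contour."""
    if stroke_px < 1:
        raise ValueError("stroke_px must be >= 1")
    placed = place_mask(mask, out_size).astype(bool)
    d_in = ndi.distance_transform_edt(placed)
    d_out = ndi.distance_transform_edt(~placed)
    inner = int(np.ceil(stroke_px / 2))
    outer = stroke_px // 2
    band = (placed & (d_in <= inner)) | (~placed & (d_out <= outer))
    if not (placed & (d_in > inner)).any():
        raise ValueError("stroke too wide: interior vanishes")
    img = _blank(out_size, (255, 255, 255))
    img[band] = (0, 0, 0)
    rec = record or StimulusRecord(shape_label="", manipulation="outline",
                                   params={"stroke_px": stroke_px})
    return StimulusImage(pixels=img, record=rec)


def render_texture_chimera(mask, texture, out_size: tuple = DEFAULT_CANVAS,
                           record: StimulusRecord | None = None) -> StimulusImage:
    """Cue-conflict stimulus: one category's shape filled with another
    category's surface texture, on uniform white.

    The texture is tiled if smaller than the mask bounding box and
    center-cropped if larger (tiling avoids introducing scale cues).
    """
    tex = np.asarray(texture)
    if tex.size == 0:
        raise ValueError("empty texture")
    if tex.ndim == 2:
        tex = np.stack([tex] * 3, axis=-1)
    placed = place_mask(mask, out_size).astype(bool)
    rows = np.any(placed, axis=1)
    cols = np.any(placed, axis=0)
    r0, r1 = np.where(rows)[0][[0, -1]]
    c0, c1 = np.where(cols)[0][[0, -1]]
    bh, bw = r1 - r0 + 1, c1 - c0 + 1
    reps = (int(np.ceil(bh / tex.shape[0])), int(np.ceil(bw / tex.shape[1])), 1)
    tiled = np.tile(tex, reps)
    tr0 = (tiled.shape[0] - bh) // 2
    tc0 = (tiled.shape[1] - bw) // 2
    patch = tiled[tr0:tr0 + bh, tc0:tc0 + bw]
    img = _blank(out_size, (255, 255, 255))
    region = placed[r0:r1 + 1, c0:c1 + 1]
    sub = img[r0:r1 + 1, c0:c1 + 1]
    sub[region] = patch[region]
    rec = record or StimulusRecord(shape_label="", manipulation="chimera",
                                   texture_label="")
    return StimulusImage(pixels=img, record=rec)


# ---------------------------------------------------------------------------
# manipulation reports


def manipulation_report(original, manipulated, m: int = G.DEFAULT_EFD_ORDER,
                        exclude_segments: list | None = None,
                        params: dict | None = None) -> G.ManipulationReport:
    """Quantify what a manipulation did to global shape vs local features.

    Global: elliptic-Fourier L2 distance (largest component vs largest
    component).  Local: chi-square distance between pooled arc-weighted
    curvature histograms over all components, with vertices near
    ``exclude_segments`` (artificial cut edges) given zero weight on the
    manipulated side.
    """
    d_orig = G.elliptic_fourier(G.extract_contour(original), m=m)
    d_new = G.elliptic_fourier(G.extract_contour(manipulated), m=m)
    gdist = G.global_shape_distance(d_orig, d_new)
    h_orig = G.mask_curvature_histogram(original, all_components=True)
    h_new = G.mask_curvature_histogram(manipulated, all_components=True,
                                       exclude_segments=exclude_segments)
    ldist = G.local_feature_distance(h_orig, h_new)
    area_ratio = float(np.asarray(manipulated).sum() / np.asarray(original).sum())
    return G.ManipulationReport(global_distance=gdist, local_distance=ldist,
                                area_ratio=area_ratio, params=params or {})


# ---------------------------------------------------------------------------
# part scrambling


def _transform_piece(sub: np.ndarray, segs_local: list, k_rot: int, mirror: bool):
    """Rotate a cropped piece by k*90 degrees (optionally mirror), mapping
    its cut-segment endpoints through the same transform."""
    out = sub
    pts = [(np.asarray(p0, float), np.asarray(p1, float)) for p0, p1 in segs_local]

    def rot_pts(pts, w):
        # np.rot90 once: (r, c) -> (w - 1 - c, r)
        return [((w - 1 - p0[1], p0[0]), (w - 1 - p1[1], p1[0])) for p0, p1 in pts]

    def mir_pts(pts, w):
        return [((p0[0], w - 1 - p0[1]), (p1[0], w - 1 - p1[1])) for p0, p1 in pts]

    if mirror:
        pts = mir_pts(pts, out.shape[1])
        out = np.fliplr(out)
    for _ in range(k_rot % 4):
        w = out.shape[1]
        pts = rot_pts(pts, w)
        out = np.rot90(out)
    pts = [(np.asarray(a, float), np.asarray(b, float)) for a, b in pts]
    return out, pts


def _cut_piece(piece: np.ndarray, rng: np.random.Generator, min_frac: float = 0.15):
    """Split a piece along a random straight chord; returns two sides and
    the chord segment endpoints (global coordinates)."""
    coords = np.argwhere(piece)
    centroid = coords.mean(axis=0)
    area = len(coords)
    for _ in range(40):
        angle = rng.uniform(0, np.pi)
        direction = np.array([np.sin(angle), np.cos(angle)])
        normal = np.array([-direction[1], direction[0]])
        spread = coords @ normal
        offset = rng.uniform(np.quantile(spread, 0.25), np.quantile(spread, 0.75))
        side = (coords @ normal) - offset
        n_pos = int((side >= 0).sum())
        if min(n_pos, area - n_pos) < min_frac * area:
            continue
        a = np.zeros_like(piece)
        b = np.zeros_like(piece)
        pos = coords[side >= 0]
        neg = coords[side < 0]
        a[pos[:, 0], pos[:, 1]] = 1
        b[neg[:, 0], neg[:, 1]] = 1
        on_line = coords[np.abs(side) <= 1.0]
        t = on_line @ direction
        p0 = direction * t.min() + normal * offset
        p1 = direction * t.max() + normal * offset
        return a, b, (p0, p1)
    raise RuntimeError("could not find a balanced cut chord")


def part_scramble(mask, n_parts: int = 3, seed: int = 0,
                  allow_mirror: bool = False, gap_px: int = 2,
                  max_place_tries: int = 400):
    """Cut a figure into ``n_parts`` pieces along straight chords and
    rigidly rearrange them (translation + 90-degree rotations) without
    overlap on the same canvas.

    Preserves local contour curvature exactly (90-degree raster rotations
    are lossless) while destroying the global configuration; the straight
    cut edges are recorded and excluded from the local-feature statistic
    in the returned report.  Deterministic given ``(mask, n_parts, seed)``.

    Returns ``(scrambled_mask, ManipulationReport)``.
    """
    m = np.asarray(mask).astype(np.uint8)
    if not m.any():
        raise ValueError("no foreground: empty mask")
    if not 1 <= n_parts <= 8:
        raise ValueError("n_parts must be in 1..8 (1 = rigid transform only)")
    rng = np.random.default_rng(seed)
    canvas = m.shape

    # iteratively cut the largest piece; each piece carries its cut segments
    pieces: list[tuple[np.ndarray, list]] = [(m.copy(), [])]
    while len(pieces) < n_parts:
        pieces.sort(key=lambda p: p[0].sum(), reverse=True)
        big, segs = pieces.pop(0)
        a, b, seg = _cut_piece(big, rng)
        pieces.append((a, segs + [seg]))
        pieces.append((b, segs + [seg]))

    # crop each piece and localize its segments
    cropped = []
    for piece, segs in pieces:
        rows = np.any(piece, axis=1)
        cols = np.any(piece, axis=0)
        r0, r1 = np.where(rows)[0][[0, -1]]
        c0, c1 = np.where(cols)[0][[0, -1]]
        sub = piece[r0:r1 + 1, c0:c1 + 1]
        local = [((p0[0] - r0, p0[1] - c0), (p1[0] - r0, p1[1] - c0))
                 for p0, p1 in segs]
        cropped.append((sub, local))
    cropped.sort(key=lambda p: p[0].sum(), reverse=True)

    H, W = canvas
    out = placed_segments = None
    # random placement can fragment the free space; restart the whole
    # arrangement with fresh rotations/positions when that happens
    for _attempt in range(30):
        out = np.zeros(canvas, dtype=np.uint8)
        occupied = np.zeros(canvas, dtype=bool)
        placed_segments = []
        ok = True
        for sub, local in cropped:
            k_rot = int(rng.integers(0, 4))
            mirror = bool(allow_mirror and rng.integers(0, 2))
            piece, segs = _transform_piece(sub, local, k_rot, mirror)
            ph, pw = piece.shape
            if ph > H or pw > W:
                raise RuntimeError("piece larger than canvas; use a larger canvas")
            footprint = (ndi.binary_dilation(piece, iterations=gap_px)
                         if gap_px else piece.astype(bool))
            placed = None
            for _ in range(max_place_tries):
                orr = int(rng.integers(0, H - ph + 1))
                occ = int(rng.integers(0, W - pw + 1))
                if not (occupied[orr:orr + ph, occ:occ + pw] & footprint).any():
                    placed = (orr, occ)
                    break
            if placed is None:
                # deterministic fallback: scan a coarse grid for any
                # feasible location before restarting
                for orr in range(0, H - ph + 1, 4):
                    for occ in range(0, W - pw + 1, 4):
                        if not (occupied[orr:orr + ph, occ:occ + pw] & footprint).any():
                            placed = (orr, occ)
                            break
                    if placed:
                        break
            if placed is None:
                ok = False
                break
            orr, occ = placed
            out[orr:orr + ph, occ:occ + pw] |= piece
            occupied[orr:orr + ph, occ:occ + pw] |= footprint.astype(bool)
            placed_segments += [((p0[0] + orr, p0[1] + occ), (p1[0] + orr, p1[1] + occ))
                                for p0, p1 in segs]
        if ok:
            break
    else:
        raise RuntimeError("could not place all pieces without overlap; "
                           "use a larger canvas or fewer parts")
    report = manipulation_report(
        m, out, exclude_segments=placed_segments,
        params={"n_parts": n_parts, "seed": seed, "allow_mirror": allow_mirror})
    return out, report


# ---------------------------------------------------------------------------
# serration


def _min_feature_halfwidth(mask) -> float:
    """Half the minimal feature width: a low quantile of the distance
    transform along the shape's skeleton (robust to skeleton spurs)."""
    m = np.asarray(mask).astype(bool)
    dist = ndi.distance_transform_edt(m)
    skel = _morph.skeletonize(m)
    vals = dist[skel]
    if vals.size == 0:
        return float(dist.max())
    # a low quantile flags genuinely thin necks without being dominated by
    # the medial-axis tails that run into sharp corners
    return float(np.quantile(vals, 0.25))


def serrate(mask, amplitude_px: float | None = None, period_px: float | None = None):
    """Displace the bounding contour along its outward normal by a
    triangular ("sawtooth") wave in arc length, then re-rasterize.

    Destroys local edge curvature while leaving the global configuration
    intact: with the default period (5% of perimeter) the serration lives
    at contour frequencies far above the low elliptic-Fourier harmonics.
    Defaults: amplitude = 3% of the bounding-box diagonal, period = 5% of
    the perimeter.  A triangular wave adds and removes approximately equal
    area, so foreground area is conserved to a few percent.

    Returns ``(serrated_mask, ManipulationReport)``.
    """
    m = np.asarray(mask).astype(np.uint8)
    if not m.any():
        raise ValueError("no foreground: empty mask")
    v = G.extract_contour(m)
    length = G.contour_length(v)
    rows = np.any(m, axis=1)
    cols = np.any(m, axis=0)
    bh = int(np.ptp(np.where(rows)[0])) + 1
    bw = int(np.ptp(np.where(cols)[0])) + 1
    halfwidth = _min_feature_halfwidth(m)
    if amplitude_px is None:
        # default 3% of the bounding-box diagonal, capped below the
        # feature-width bound so slender shapes stay serratable
        amplitude_px = min(0.03 * float(np.hypot(bh, bw)), 0.8 * halfwidth)
    elif amplitude_px >= halfwidth:
        raise ValueError(
            f"amplitude {amplitude_px:.1f} px >= half the minimal feature "
            f"width ({halfwidth:.1f} px); shape would self-destruct")
    if period_px is None:
        period_px = 0.05 * length
    if period_px < 4:
        raise ValueError("period_px must be >= 4")

    n = max(G.DEFAULT_RESAMPLE_N, int(np.ceil(length / min(1.0, period_px / 8))))
    r = G.resample_arclength(v, n)
    seg = np.hypot(*np.diff(np.vstack([r, r[:1]]), axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg[:-1])])
    # periodic triangular wave in [-1, 1]; integer number of periods so the
    # wave closes smoothly around the contour
    n_periods = max(1, int(round(length / period_px)))
    phase = (s / length * n_periods) % 1.0
    tri = 1.0 - 4.0 * np.abs(phase - 0.5)
    if amplitude_px > 0:
        tangent = np.vstack([r[1:], r[:1]]) - np.vstack([r[-1:], r[:-1]])
        tangent /= np.hypot(*tangent.T)[:, None]
        normal = np.stack([tangent[:, 1], -tangent[:, 0]], axis=1)
        # orient outward: the offset curve must enclose more area
        probe = r + normal
        if abs(G.signed_area(probe)) < abs(G.signed_area(r)):
            normal = -normal
        new_v = r + amplitude_px * tri[:, None] * normal
        new_v[:, 0] = np.clip(new_v[:, 0], 0, m.shape[0] - 1)
        new_v[:, 1] = np.clip(new_v[:, 1], 0, m.shape[1] - 1)
        out = G.rasterize(new_v, *m.shape)
        out = G.largest_component(out)  # repair any self-intersection
    else:
        out = G.rasterize(r, *m.shape)
    report = manipulation_report(
        m, out, params={"amplitude_px": float(amplitude_px),
                        "period_px": float(period_px)})
    return out, report


# ---------------------------------------------------------------------------
# I/O: PNG stimuli + JSON provenance sidecars + CSV manifests


def save_stimulus(stim: StimulusImage, path) -> None:
    """Write the raster as PNG and the record as a JSON sidecar."""
    from PIL import Image

    path = Path(path)
    Image.fromarray(stim.pixels).save(path)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(stim.record.to_dict(), indent=1))


def load_stimulus(path) -> StimulusImage:
    from PIL import Image

    path = Path(path)
    pixels = np.asarray(Image.open(path).convert("RGB"))
    record = StimulusRecord.from_dict(json.loads(path.with_suffix(".json").read_text()))
    return StimulusImage(pixels=pixels, record=record)


def write_manifest(records: list, path) -> None:
    """One StimulusRecord per row; params serialized as JSON."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["item_id", "shape_label", "texture_label", "manipulation",
                         "fg", "bg", "params", "seed"])
        for rec in records:
            writer.writerow([rec.item_id, rec.shape_label, rec.texture_label or "",
                             rec.manipulation, json.dumps(list(rec.colorway.fg)),
                             json.dumps(list(rec.colorway.bg)),
                             json.dumps(rec.params, sort_keys=True),
                             "" if rec.seed is None else rec.seed])
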