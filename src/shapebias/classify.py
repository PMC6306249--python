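"""Classifier contract and toy classifiers embodying the two hypotheses.

Any classifier under audit must satisfy one contract: RGB raster (or
binary mask) in, probability vector over a fixed label vocabulary out.
Two deterministic nearest-centroid classifiers embody the competing
recognition hypotheses:

* ``feature_kind="curvature"`` — a *local contour feature* recognizer: its
  feature is the arc-length-weighted curvature histogram pooled over all
  foreground components, indifferent to how parts are arranged.
* ``feature_kind="efd"`` — a *global shape* recognizer: its feature is the
  normalized elliptic Fourier descriptor of the largest component's
  bounding contour.

Both follow the scikit-learn estimator API (``fit`` / ``predict`` /
``predict_proba``, ``get_params`` / ``set_params``), so they compose with
sklearn pipelines and model selection.  Probabilities are
``softmax(-distance / temperature)`` over class centroids.

External pretrained networks are wired in through
:func:`external_adapter_contract`; core functionality never imports one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import geometry as G

__all__ = [
    "ProbsDiagnostics",
    "validate_probs",
    "image_to_mask",
    "ToyShapeClassifier",
    "fit_toy",
    "predict_toy",
    "external_adapter_contract",
    "MockAdapter",
]

PROB_SUM_TOL = 1e-6


@dataclass(frozen=True)
class ProbsDiagnostics:
    """Result of validating a probability vector against the contract."""

    ok: bool
    total: float
    min_value: float
    message: str = ""


def validate_probs(probs) -> ProbsDiagnostics:
    """Check nonnegativity and unit sum (|sum - 1| <= 1e-6)."""
    p = np.asarray(probs, dtype=float)
    total = float(p.sum())
    min_value = float(p.min()) if p.size else 0.0
    problems = []
    if p.size == 0:
        problems.append("empty vector")
    if min_value < 0:
        problems.append(f"negative entry {min_value:.3g}")
    if abs(total - 1.0) > PROB_SUM_TOL:
        problems.append(f"sum deviates from 1 by {total - 1.0:+.3g}")
    return ProbsDiagnostics(ok=not problems, total=total, min_value=min_value,
                            message="; ".join(problems))


def image_to_mask(image) -> np.ndarray:
    """Reduce a rendered stimulus to a binary foreground mask.

    Foreground = any pixel differing from the modal border color; matches
    the generators' uniform-background contract.
    """
    img = np.asarray(image)
    if img.ndim == 2:
        if np.isin(np.unique(img), [0, 1]).all():
            return img.astype(np.uint8)
        img = img[..., None]
    border = np.concatenate([img[0].reshape(-1, img.shape[-1]),
                             img[-1].reshape(-1, img.shape[-1]),
                             img[:, 0].reshape(-1, img.shape[-1]),
                             img[:, -1].reshape(-1, img.shape[-1])])
    colors, counts = np.unique(border, axis=0, return_counts=True)
    bg = colors[counts.argmax()]
    mask = (img != bg).any(axis=-1).astype(np.uint8)
    if not mask.any():
        raise ValueError("no foreground: image is uniform background")
    return mask


def _extract_feature(mask, feature_kind: str, bins: np.ndarray, m: int,
                     spike_thresh: float = 0.0, spike_win_px: float = 5.0) -> np.ndarray:
    if feature_kind == "curvature":
        h = G.mask_curvature_histogram(mask, bins=bins, all_components=True,
                                       spike_thresh=spike_thresh,
                                       spike_win_px=spike_win_px,
                                       allow_empty=True)
        # A local-feature recognizer keys on the distribution of *curved*
        # micro-features, so two kinds of arc are discounted: the
        # effectively-straight central band (no local signature; also makes
        # the feature blind to added straight edges) and, via spike_thresh,
        # corner-like singularities (isolated junk junctions rather than
        # repeatable class features).  The rest is renormalized.
        n = len(h)
        keep = np.ones(n, dtype=bool)
        keep[n // 2] = False
        h = h[keep]
        total = h.sum()
        return h / total if total > 0 else h
    if feature_kind == "efd":
        desc = G.elliptic_fourier(G.extract_contour(G.largest_component(mask)), m=m)
        return desc.harmonics.ravel()
    raise ValueError("feature_kind must be 'curvature' or 'efd'")


def _efd_gauge_variants(flat: np.ndarray, m: int) -> np.ndarray:
    """Both residual start-point gauges of a flattened (m, 4) descriptor."""
    harm = flat.reshape(m, 4)
    return np.stack([flat, G.gauge_flip(harm).ravel()])


class ToyShapeClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-centroid classifier over contour features.

    Parameters
    ----------
    feature_kind : {"curvature", "efd"}
        Which recognition hypothesis to embody (local contour features vs
        global shape).
    temperature : float
        Softmax temperature over negative centroid distances.
    n_bins, kappa_min, kappa_max : int, float, float
        Curvature histogram binning: ``n_bins`` log-spaced bins per sign
        over ``kappa_min <= |kappa| <= kappa_max`` rad/px (see
        :func:`shapebias.geometry.log_curvature_bins`).
    spike_thresh, spike_win_px : float
        Corner discounting for the curvature feature: arc within
        ``spike_win_px`` of a raw-curvature spike above ``spike_thresh``
        rad/px gets zero weight.  Set ``spike_thresh=0`` to disable.
    m : int
        Number of elliptic Fourier harmonics for the global-shape feature.

    Attributes
    ----------
    classes_ : ndarray of class labels (the vocabulary, sorted).
    centroids_ : (K, d) per-class mean feature vectors.

    Notes
    -----
    Centroid distance is symmetric chi-square for curvature histograms
    (the natural metric between normalized histograms, and less sensitive
    than Euclidean to mass injected into a few bins by contour damage) and
    Euclidean for elliptic Fourier descriptors.
    """

    def __init__(self, feature_kind: str = "curvature", temperature: float = 1.0,
                 n_bins: int = 10, kappa_min: float = 0.012, kappa_max: float = 0.35,
                 spike_thresh: float = 0.35, spike_win_px: float = 5.0, m: int = 10):
        self.feature_kind = feature_kind
        self.temperature = temperature
        self.n_bins = n_bins
        self.kappa_min = kappa_min
        self.kappa_max = kappa_max
        self.spike_thresh = spike_thresh
        self.spike_win_px = spike_win_px
        self.m = m

    def _bins(self) -> np.ndarray:
        return G.log_curvature_bins(self.kappa_min, self.kappa_max, self.n_bins)

    def _features(self, X) -> np.ndarray:
        bins = self._bins()
        return np.array([
            _extract_feature(image_to_mask(x), self.feature_kind, bins, self.m,
                             spike_thresh=self.spike_thresh,
                             spike_win_px=self.spike_win_px)
            for x in X
        ])

    def fit(self, X, y):
        """Fit per-class centroid features from masks or rendered images.

        ``X`` is a sequence of 2D binary masks or HxWx3 rasters; ``y`` the
        class labels (>= 1 exemplar per class required).  Deterministic.
        """
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        y = np.asarray(y)
        if len(X) != len(y) or len(y) == 0:
            raise ValueError("X and y must be equal-length and nonempty")
        feats = self._features(X)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 1:
            raise ValueError("need at least one class")
        centroids = []
        for c in self.classes_:
            fc = feats[y == c]
            if self.feature_kind == "efd":
                # align each exemplar's residual start-point gauge to the
                # class anchor before averaging, else centroids smear
                anchor = fc[0]
                fc = np.array([
                    min(_efd_gauge_variants(v, self.m),
                        key=lambda g: float(np.linalg.norm(g - anchor)))
                    for v in fc
                ])
            centroids.append(fc.mean(axis=0))
        self.centroids_ = np.array(centroids)
        self.n_features_in_ = feats.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "centroids_")
        feats = self._features(X)
        if self.feature_kind == "efd":
            d = np.array([
                np.linalg.norm(_efd_gauge_variants(f, self.m)[:, None, :]
                               - self.centroids_[None], axis=-1).min(axis=0)
                for f in feats
            ])
        else:
            den = feats[:, None, :] + self.centroids_[None]
            num = (feats[:, None, :] - self.centroids_[None]) ** 2
            d = 0.5 * np.where(den > 0, num / np.where(den > 0, den, 1.0),
                               0.0).sum(axis=-1)
        return -d / self.temperature

    def predict_proba(self, X) -> np.ndarray:
        """Softmax over negative centroid distances; rows pass validate_probs."""
        scores = self.decision_function(X)
        scores -= scores.max(axis=1, keepdims=True)
        e = np.exp(scores)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    # -- JSON serialization (centroids, binning, flags) --------------------

    def to_json(self) -> str:
        check_is_fitted(self, "centroids_")
        return json.dumps({
            "params": self.get_params(),
            "classes": [str(c) for c in self.classes_],
            "centroids": self.centroids_.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "ToyShapeClassifier":
        d = json.loads(text)
        clf = cls(**d["params"])
        clf.classes_ = np.array(d["classes"])
        clf.centroids_ = np.array(d["centroids"])
        clf.n_features_in_ = clf.centroids_.shape[1]
        return clf

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "ToyShapeClassifier":
        return cls.from_json(Path(path).read_text())


# thin functional wrappers -------------------------------------------------


def fit_toy(catalog_masks: dict, feature_kind: str = "curvature",
            temperature: float = 1.0) -> ToyShapeClassifier:
    """Fit a toy classifier from a ``{label: [masks]}`` catalog split."""
    X, y = [], []
    for label, masks in catalog_masks.items():
        if len(masks) == 0:
            raise ValueError(f"class {label!r} has zero exemplars")
        X.extend(masks)
        y.extend([label] * len(masks))
    return ToyShapeClassifier(feature_kind=feature_kind,
                              temperature=temperature).fit(X, y)


def predict_toy(model: ToyShapeClassifier, image_or_mask) -> np.ndarray:
    """Probability vector (aligned to ``model.classes_``) for one input."""
    return model.predict_proba([image_or_mask])[0]


# external adapters --------------------------------------------------------


def external_adapter_contract() -> dict:
    """The callable contract an external pretrained network must satisfy.

    Adapters are discovered by configuration key and are never imported by
    core code; the audit pipeline only ever calls the documented surface.
    """
    return {
        "input": "HxWx3 uint8 RGB raster",
        "output": "1D float array over the adapter's own vocabulary, "
                  "nonnegative, summing to 1 within 1e-6 (validate_probs)",
        "attributes": {
            "classes_": "ordered label vocabulary the output aligns to",
        },
        "methods": {
            "predict_proba(images) -> (n, K) array": "batch probabilities",
        },
        "notes": "vocabulary labels must match manifest shape/texture labels "
                 "for metric computation; mismatches are a manifest-join error",
    }


class MockAdapter:
    """A trivial contract-conforming adapter for pipeline tests: returns a
    fixed probability vector for every image."""

    def __init__(self, classes, probs):
        self.classes_ = np.asarray(classes)
        self._probs = np.asarray(probs, dtype=float)
        if len(self.classes_) != len(self._probs):
            raise ValueError("classes and probs must align")

    def predict_proba(self, images) -> np.ndarray:
        return np.tile(self._probs, (len(images), 1))
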