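"""Vessel binarization: trainable pixel classification plus threshold fallbacks.

The study workflow trains an interactive pixel classifier from scribble
annotations (strokes drawn inside vessels and over background) on one
representative angiogram per layer, then applies that classifier to every
other image of the same layer. Here that step is an sklearn-compatible
estimator: a bagged-decision-tree (random forest) rule over a multiscale
per-pixel feature stack — raw intensity, Gaussian-smoothed intensity,
gradient magnitude, and the two Hessian eigenvalues at each smoothing scale.
All convolutions use reflective padding; identical scribbles and seed give
bit-identical masks.

Otsu and fixed thresholds are provided as deterministic fallbacks so the
downstream morphometry is usable without any training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted
from skimage.filters import threshold_otsu

from .images import AngioImage, VesselMask

DEFAULT_SCALES = (0.0, 1.0, 2.0, 4.0)


@dataclass(frozen=True)
class Scribbles:
    """Sparse training strokes: (row, col) pixels labeled vessel / background."""

    vessel_strokes: tuple[tuple[int, int], ...]
    background_strokes: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        v = set(map(tuple, self.vessel_strokes))
        b = set(map(tuple, self.background_strokes))
        if v & b:
            raise ValueError("vessel and background strokes must be disjoint")
        object.__setattr__(self, "vessel_strokes", tuple(sorted(v)))
        object.__setattr__(self, "background_strokes", tuple(sorted(b)))


def _deriv_images(img: np.ndarray, sigma: float):
    """(smoothed, dy, dx, dyy, dyx, dxx) at one scale, reflective boundary."""
    if sigma > 0:
        sm = ndimage.gaussian_filter(img, sigma, mode="reflect")
    else:
        sm = img.copy()
    pad = np.pad(sm, 1, mode="reflect")
    dy = (pad[2:, 1:-1] - pad[:-2, 1:-1]) / 2.0
    dx = (pad[1:-1, 2:] - pad[1:-1, :-2]) / 2.0
    dyy = pad[2:, 1:-1] - 2.0 * sm + pad[:-2, 1:-1]
    dxx = pad[1:-1, 2:] - 2.0 * sm + pad[1:-1, :-2]
    dyx = (pad[2:, 2:] - pad[2:, :-2] - pad[:-2, 2:] + pad[:-2, :-2]) / 4.0
    return sm, dy, dx, dyy, dyx, dxx


def extract_pixel_features(image: AngioImage | np.ndarray,
                           scales=DEFAULT_SCALES) -> np.ndarray:
    """Per-pixel feature stack, shape (H, W, 1 + 4·len(scales)).

    Channels: raw intensity; then per scale — smoothed intensity, gradient
    magnitude, larger and smaller Hessian eigenvalue.
    """
    img = image.pixels if isinstance(image, AngioImage) else np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2D grid")
    scales = tuple(scales)
    if not scales:
        raise ValueError("at least one scale required")
    if any(s < 0 for s in scales):
        raise ValueError("scales must be non-negative")
    img = img.astype(np.float64)
    chans = [img]
    for s in scales:
        sm, dy, dx, dyy, dyx, dxx = _deriv_images(img, s)
        grad = np.hypot(dy, dx)
        # closed-form eigenvalues of the 2x2 symmetric Hessian
        tr = dyy + dxx
        disc = np.sqrt(((dyy - dxx) / 2.0) ** 2 + dyx ** 2)
        chans.extend([sm, grad, tr / 2.0 + disc, tr / 2.0 - disc])
    return np.stack(chans, axis=-1)


class PixelClassifier(BaseEstimator, ClassifierMixin):
    """Scribble-trained vessel/background pixel classifier.

    Parameters
    ----------
    feature_scales : tuple of float
        Gaussian smoothing scales (px) of the feature stack; 0 keeps the raw
        channel.
    n_estimators : int
        Trees in the bagged ensemble.
    seed : int
        Fixes bagging and feature subsampling; identical scribbles + seed
        give identical predictions.
    """

    def __init__(self, feature_scales=DEFAULT_SCALES, n_estimators: int = 50,
                 seed: int = 0):
        self.feature_scales = feature_scales
        self.n_estimators = n_estimators
        self.seed = seed

    def fit(self, image: AngioImage | np.ndarray, scribbles: Scribbles):
        if not scribbles.vessel_strokes or not scribbles.background_strokes:
            raise ValueError("both vessel and background strokes required")
        feats = extract_pixel_features(image, self.feature_scales)
        v = np.asarray(scribbles.vessel_strokes)
        b = np.asarray(scribbles.background_strokes)
        X = np.vstack([feats[v[:, 0], v[:, 1]], feats[b[:, 0], b[:, 1]]])
        y = np.concatenate([np.ones(len(v), dtype=int), np.zeros(len(b), dtype=int)])
        self.model_ = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.seed, n_jobs=1)
        self.model_.fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, image: AngioImage | np.ndarray) -> np.ndarray:
        """Binary vessel map (H, W) for a whole image."""
        check_is_fitted(self, "model_")
        feats = extract_pixel_features(image, self.feature_scales)
        h, w, c = feats.shape
        pred = self.model_.predict(feats.reshape(-1, c))
        return pred.reshape(h, w).astype(np.uint8)


def train_classifier(image: AngioImage | np.ndarray, scribbles: Scribbles,
                     seed: int = 0, scales=DEFAULT_SCALES) -> PixelClassifier:
    """Convenience wrapper: fit a :class:`PixelClassifier` on one image."""
    return PixelClassifier(feature_scales=tuple(scales), seed=seed).fit(image, scribbles)


def binarize(image: AngioImage, classifier: PixelClassifier | None = None,
             method: str = "otsu", threshold: float | None = None,
             min_object_px: int = 0) -> VesselMask:
    """Binary vessel mask via trained classifier, Otsu, or a fixed threshold.

    ``min_object_px`` optionally removes connected components smaller than
    that size (off by default — the reference workflow does no cleaning).
    """
    img = image.pixels
    prov: dict = {"method": method}
    if method == "classifier":
        if classifier is None:
            raise ValueError("method='classifier' requires a trained classifier")
        mask = classifier.predict(image)
        prov["seed"] = classifier.seed
        prov["scales"] = ",".join(str(s) for s in classifier.feature_scales)
    elif method == "otsu":
        if img.min() == img.max():  # constant image has no foreground
            mask = np.zeros_like(img, dtype=np.uint8)
        else:
            t = threshold_otsu(img)
            mask = (img > t).astype(np.uint8)
            prov["threshold"] = float(t)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        mask = (img > threshold).astype(np.uint8)
        prov["threshold"] = float(threshold)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    if min_object_px > 0:
        from skimage.morphology import remove_small_objects

        mask = remove_small_objects(mask.astype(bool), min_object_px).astype(np.uint8)
        prov["min_object_px"] = min_object_px
    return VesselMask(mask, image.scale_um_per_px, image.layer_tag, provenance=prov)
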