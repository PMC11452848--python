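"""Fruit/background segmentation and intensity clustering.

The scene is a dark fruit on a bright backdrop, so segmentation is: convert
to gray (BT.601 luminance), keep pixels inside a [lower, upper] gray band
(defaults 0-185; optionally Otsu picks the upper bound), fill interior
holes, clean speckle with a 3x3 opening + closing, and count the remaining
foreground pixels as the fruit size.

``cluster_intensities`` is a diagnostic 1-D k-means over gray levels that
recovers the three natural intensity populations of a weigh-plate scene —
background, shadow and fruit — reporting each cluster's mean and population
variance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi

__all__ = [
    "ThresholdConfig",
    "ClusterModel",
    "to_gray",
    "otsu_threshold",
    "threshold_binary",
    "fill_holes",
    "morph_clean",
    "fruit_pixel_count",
    "pixel_stats",
    "cluster_intensities",
    "segment_fruit",
]

_SQUARE3 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ThresholdConfig:
    """Gray band kept as foreground; fruit is darker than the background."""

    upper: int = 185
    lower: int = 0
    use_otsu: bool = False

    def __post_init__(self) -> None:
        for name, v in (("upper", self.upper), ("lower", self.lower)):
            if not 0 <= v <= 255:
                raise ValueError(f"{name} threshold must be in [0,255], got {v}")
        if self.lower > self.upper:
            raise ValueError(f"lower ({self.lower}) must not exceed upper ({self.upper})")


@dataclass
class ClusterModel:
    """1-D k-means result: per-cluster mean, population variance, labels."""

    k: int
    means: np.ndarray
    variances: np.ndarray
    assignments: np.ndarray
    n_iter: int = 0
    wcss_history: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(
            {"k": self.k, "means": self.means.tolist(), "variances": self.variances.tolist()},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(doc + "\n")
        return doc


def to_gray(image: np.ndarray) -> np.ndarray:
    """BT.601 luminance 0.299R + 0.587G + 0.114B, rounded to uint8."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {img.shape}")
    gray = 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]
    return np.clip(np.floor(gray + 0.5), 0, 255).astype(np.uint8)


def otsu_threshold(gray: np.ndarray) -> int:
    """Gray level t maximizing between-class variance of {p <= t} vs {p > t}.

    Ties are broken toward the smallest t.  A constant image has no
    two-class split and is rejected.
    """
    gray = np.asarray(gray)
    hist = np.bincount(gray.ravel().astype(np.int64), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("Otsu threshold undefined for a constant image")
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)
    total = w0[-1]
    m0 = np.cumsum(hist * levels)
    mean_total = m0[-1]
    w1 = total - w0
    # between-class variance w0*w1*(mu0-mu1)^2, defined where both classes nonempty
    valid = (w0 > 0) & (w1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (mean_total - m0) / w1
    sigma_b = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    return int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer


def threshold_binary(gray: np.ndarray, config: ThresholdConfig | None = None) -> np.ndarray:
    """Foreground = pixels with lower <= p <= upper (both inclusive).

    With ``use_otsu`` the upper bound is replaced by the Otsu threshold, so
    the darker class becomes foreground.
    """
    config = config or ThresholdConfig()
    gray = np.asarray(gray)
    upper = otsu_threshold(gray) if config.use_otsu else config.upper
    return (gray >= config.lower) & (gray <= upper)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Flip background regions not connected to the image border to foreground.

    Background flood-fill uses 4-connectivity (the complement of the
    8-connected foreground convention).  Foreground never shrinks.
    """
    return ndi.binary_fill_holes(np.asarray(mask, dtype=bool))


def morph_clean(mask: np.ndarray) -> np.ndarray:
    """Binary opening then closing with a 3x3 square; removes speckle."""
    mask = np.asarray(mask, dtype=bool)
    return ndi.binary_closing(ndi.binary_opening(mask, _SQUARE3), _SQUARE3)


def fruit_pixel_count(mask: np.ndarray) -> int:
    """Foreground pixel count — the fruit size in pixels."""
    return int(np.asarray(mask, dtype=bool).sum())


def pixel_stats(values) -> tuple[float, float]:
    """Mean and population variance (divisor n) of a nonempty value list."""
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("pixel_stats needs at least one value")
    mu = float(v.mean())
    return mu, float(np.mean((v - mu) ** 2))


def cluster_intensities(
    gray: np.ndarray,
    k: int = 3,
    max_iter: int = 100,
    tol: float = 1e-4,
    seed: int = 0,
) -> ClusterModel:
    """1-D k-means over gray levels (default k=3: background/shadow/fruit).

    Deterministic initialization at k evenly spaced quantiles of the sorted
    intensities; Lloyd iterations assign each pixel to the nearest mean and
    recompute means until the largest mean shift is below ``tol`` gray
    levels or ``max_iter`` is reached.  An emptied cluster is re-seeded at
    the intensity farthest from the surviving means.  Means are returned in
    ascending order with per-cluster population variances.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    values = np.asarray(gray, dtype=np.float64).ravel()
    uniq = np.unique(values)
    if uniq.size < k:
        raise ValueError(f"image has {uniq.size} distinct values, fewer than k={k}")

    srt = np.sort(values)
    # centered quantile positions (i + 0.5)/k of the sorted data
    means = srt[((np.arange(k) + 0.5) / k * values.size).astype(int)].astype(np.float64)
    means = np.unique(means)
    while means.size < k:  # duplicate quantiles: re-seed at farthest point
        d = np.min(np.abs(values[:, None] - means[None, :]), axis=1)
        means = np.append(means, values[int(np.argmax(d))])
    means.sort()

    wcss_history: list[float] = []
    labels = np.zeros(values.size, dtype=np.int64)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        dist = np.abs(values[:, None] - means[None, :])
        labels = np.argmin(dist, axis=1)
        wcss_history.append(float(np.sum((values - means[labels]) ** 2)))
        new_means = means.copy()
        for j in range(k):
            sel = labels == j
            if sel.any():
                new_means[j] = values[sel].mean()
            else:
                d = np.min(np.abs(values[:, None] - new_means[None, :]), axis=1)
                new_means[j] = values[int(np.argmax(d))]
        shift = np.max(np.abs(new_means - means))
        means = new_means
        if shift < tol:
            break

    means = np.sort(means)
    dist = np.abs(values[:, None] - means[None, :])
    labels = np.argmin(dist, axis=1)
    variances = np.array(
        [np.mean((values[labels == j] - means[j]) ** 2) if (labels == j).any() else 0.0 for j in range(k)]
    )
    return ClusterModel(
        k=k,
        means=means,
        variances=variances,
        assignments=labels.reshape(np.asarray(gray).shape),
        n_iter=n_iter,
        wcss_history=wcss_history,
    )


def segment_fruit(image: np.ndarray, config: ThresholdConfig | None = None) -> np.ndarray:
    """Full chain: gray -> band threshold -> fill holes -> morphological clean."""
    return morph_clean(fill_holes(threshold_binary(to_gray(image), config)))
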