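"""Point-sampled fruit color and RGB -> HSI feature extraction.

A fruit's color is measured the way a sorting line does it: draw n pixels
(5-25, default 15) uniformly from inside the fruit region, average the red,
green and blue channels, then derive normalized chromaticities and the
hue/saturation/intensity coordinates:

    r = R/(R+G+B),  g = G/(R+G+B),  b = B/(R+G+B)
    I = (R+G+B)/3
    S = 1 - min(R,G,B)/I
    theta = arccos( 0.5*((r-g)+(r-b)) / (sqrt((r-g)^2+(r-b)(g-b)) + eps) )
    H = theta/(2*pi),  flipped to (2*pi - theta)/(2*pi) when b > g,
        and H = 0 for achromatic pixels (S = 0)

Averaging several points suppresses camera noise; the sampler is seeded so a
measurement can be reproduced exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EPS",
    "MIN_POINTS",
    "MAX_POINTS",
    "ColorSampleConfig",
    "FeatureVector",
    "sample_color_points",
    "mean_rgb",
    "normalize_rgb",
    "saturation",
    "intensity",
    "hue",
    "rgb_to_hsi",
    "extract_features",
]

#: guard for the zero-denominator case in the hue arccos (double-precision ulp of 1)
EPS = 2.220446049250313e-16

MIN_POINTS = 5
MAX_POINTS = 25


@dataclass(frozen=True)
class ColorSampleConfig:
    """How many color points to draw and with which seed."""

    n_points: int = 15
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not MIN_POINTS <= self.n_points <= MAX_POINTS:
            raise ValueError(
                f"n_points must be in [{MIN_POINTS},{MAX_POINTS}], got {self.n_points}"
            )


@dataclass
class FeatureVector:
    """All measured quantities for one fruit sample.

    Channel means are on the 0-255 scale; (r,g,b) are chromaticities summing
    to 1; H in [0,1), S in [0,1], I on the 0-255 scale.  ``black`` flags the
    degenerate all-zero color where chromaticities are undefined.
    """

    R_mean: float
    G_mean: float
    B_mean: float
    r: float
    g: float
    b: float
    H: float
    S: float
    I: float
    size_px: int
    weight_g: float
    black: bool = False

    def as_row(self) -> dict[str, float]:
        return {
            "R": self.R_mean, "G": self.G_mean, "B": self.B_mean,
            "r": self.r, "g": self.g, "b": self.b,
            "H": self.H, "S": self.S, "I": self.I,
            "size_px": self.size_px, "weight_g": self.weight_g,
        }


def sample_color_points(
    image: np.ndarray, roi: np.ndarray, config: ColorSampleConfig
) -> np.ndarray:
    """Draw ``n_points`` pixel values uniformly without replacement from the ROI.

    Returns an (n_points, 3) float array; identical seed gives identical
    points.  Raises if the ROI is empty or smaller than ``n_points``.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != image.shape[:2]:
        raise ValueError(f"roi shape {roi.shape} does not match image {image.shape[:2]}")
    rows, cols = np.nonzero(roi)
    if rows.size == 0:
        raise ValueError("ROI is empty: no pixels to sample color from")
    if rows.size < config.n_points:
        raise ValueError(f"ROI has {rows.size} pixels, fewer than n_points={config.n_points}")
    rng = np.random.default_rng(config.rng_seed)
    idx = rng.choice(rows.size, size=config.n_points, replace=False)
    return image[rows[idx], cols[idx]].astype(np.float64)


def mean_rgb(points: np.ndarray) -> tuple[float, float, float]:
    """Arithmetic per-channel mean of a nonempty list of (R,G,B) triples."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.size == 0:
        raise ValueError("cannot average an empty list of color points")
    m = pts.reshape(-1, 3).mean(axis=0)
    return float(m[0]), float(m[1]), float(m[2])


def normalize_rgb(R: float, G: float, B: float) -> tuple[float, float, float]:
    """Chromaticities r,g,b = channel / (R+G+B); (0,0,0) for black input."""
    if R < 0 or G < 0 or B < 0:
        raise ValueError("channel values must be nonnegative")
    total = R + G + B
    if total == 0:
        return 0.0, 0.0, 0.0
    return R / total, G / total, B / total


def intensity(R: float, G: float, B: float) -> float:
    """Intensity I = (R+G+B)/3."""
    return (R + G + B) / 3.0


def saturation(R: float, G: float, B: float) -> float:
    """Saturation S = 1 - min(R,G,B)/I; 0 for the degenerate black pixel."""
    I = intensity(R, G, B)
    if I == 0:
        return 0.0
    # clamp: min/I can exceed 1 by one ulp for achromatic input
    return min(1.0, max(0.0, 1.0 - min(R, G, B) / I))


def hue(r: float, g: float, b: float, S: float, radians: bool = False) -> float:
    """Hue from chromaticities by the geometric arccos formula.

    theta = arccos(num/(den+eps)) with num = 0.5*((r-g)+(r-b)) and
    den = sqrt((r-g)^2 + (r-b)*(g-b)); reflected to 2*pi - theta when b > g.
    Achromatic input (S = 0) maps to hue 0.  Returns theta/(2*pi) in [0,1)
    by default, or theta itself with ``radians=True``.
    """
    if S == 0:
        return 0.0
    num = 0.5 * ((r - g) + (r - b))
    den = math.sqrt((r - g) ** 2 + (r - b) * (g - b))
    theta = math.acos(max(-1.0, min(1.0, num / (den + EPS))))
    if b > g:
        theta = 2.0 * math.pi - theta
    if radians:
        return theta
    h = theta / (2.0 * math.pi)
    return h if h < 1.0 else 0.0


def rgb_to_hsi(R: float, G: float, B: float) -> tuple[float, float, float]:
    """Convenience: (H, S, I) of one RGB value via the module's primitives."""
    r, g, b = normalize_rgb(R, G, B)
    S = saturation(R, G, B)
    return hue(r, g, b, S), S, intensity(R, G, B)


def extract_features(
    image: np.ndarray,
    mask: np.ndarray,
    weight_g: float,
    config: ColorSampleConfig | None = None,
) -> FeatureVector:
    """Measure one fruit: sampled mean color, HSI, pixel size and weight.

    ``mask`` is both the color-sampling ROI and the size measurement; its
    foreground pixel count is the fruit size.  Deterministic under a fixed
    sampling seed.
    """
    config = config or ColorSampleConfig()
    points = sample_color_points(image, mask, config)
    R, G, B = mean_rgb(points)
    r, g, b = normalize_rgb(R, G, B)
    S = saturation(R, G, B)
    return FeatureVector(
        R_mean=R, G_mean=G, B_mean=B,
        r=r, g=g, b=b,
        H=hue(r, g, b, S), S=S, I=intensity(R, G, B),
        size_px=int(np.asarray(mask, dtype=bool).sum()),
        weight_g=float(weight_g),
        black=(R + G + B == 0),
    )
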