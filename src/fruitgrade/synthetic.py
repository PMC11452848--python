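"""Seeded synthetic fruit scenes with ground-truth masks, grades and weights.

Real grading rigs photograph a single fruit lying on the light background of a
weight sensor, so every frame contains three intensity populations: bright
background, a darker shadow band cast by the fruit, and the fruit itself.
This module renders that scene — an elliptical fruit with a crescent shadow on
a uniform light background, plus additive Gaussian camera noise — and samples
whole populations of labelled fruit whose color, radius and weight follow
per-grade normal distributions.  Four-grade species presets (tomato, apple,
lemon, peach) ship as YAML files; they are synthetic, chosen so grade means
are well separated, not calibrated to real produce.

All randomness flows from one integer seed through ``numpy`` generators; no
global state is touched.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

__all__ = [
    "GradeParams",
    "FruitSpec",
    "LabeledSample",
    "render_fruit_image",
    "ellipse_lattice_count",
    "sample_grade_population",
    "make_benchmark_dataset",
    "load_preset",
    "available_presets",
    "sample_fruit_spec",
    "separation_preset",
]

PRESET_SPECIES = ("tomato", "apple", "lemon", "peach")


@dataclass(frozen=True)
class GradeParams:
    """Population parameters for one quality grade of one species.

    Color is the mean fruit RGB (0-255), radius the mean ellipse semi-axis in
    pixels, weight the mean mass in grams; each with its own normal spread.
    """

    grade_index: int
    color_mean: tuple[float, float, float]
    color_sd: tuple[float, float, float] = (4.0, 4.0, 4.0)
    radius_mean_px: float = 25.0
    radius_sd_px: float = 1.0
    weight_mean_g: float = 120.0
    weight_sd_g: float = 5.0

    def __post_init__(self) -> None:
        if self.grade_index not in (1, 2, 3, 4):
            raise ValueError(f"grade_index must be 1-4, got {self.grade_index}")
        if len(self.color_mean) != 3 or not all(0 <= c <= 255 for c in self.color_mean):
            raise ValueError(f"color_mean must be an RGB triple in [0,255], got {self.color_mean}")
        if any(s < 0 for s in self.color_sd) or self.radius_sd_px < 0 or self.weight_sd_g < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.radius_mean_px <= 0 or self.weight_mean_g <= 0:
            raise ValueError("radius_mean_px and weight_mean_g must be positive")


@dataclass(frozen=True)
class FruitSpec:
    """Geometry and photometry of one rendered scene.

    ``axes`` are the ellipse semi-axes (rows, cols) in pixels; they may be
    fractional.  ``background_level`` is the uniform light-gray backdrop;
    the shadow is the fruit ellipse translated down by ``shadow_offset_px``
    rows, filled with ``background_level * (1 - shadow_darkening)``.
    """

    image_size: tuple[int, int] = (120, 160)
    center: tuple[float, float] = (60.0, 80.0)
    axes: tuple[float, float] = (25.0, 25.0)
    fruit_color: tuple[float, float, float] = (200.0, 80.0, 60.0)
    background_level: float = 235.0
    shadow_offset_px: int = 6
    shadow_darkening: float = 0.08
    noise_sd: float = 4.0

    def validate(self) -> None:
        h, w = self.image_size
        cr, cc = self.center
        a, b = self.axes
        if a <= 0 or b <= 0:
            raise ValueError(f"ellipse semi-axes must be positive, got {self.axes}")
        if not (cr - a >= 0 and cr + a + abs(self.shadow_offset_px) < h and cc - b >= 0 and cc + b < w):
            raise ValueError(
                f"ellipse (center {self.center}, axes {self.axes}, shadow offset "
                f"{self.shadow_offset_px}) does not fit inside a {h}x{w} image"
            )
        if not 0.0 <= self.shadow_darkening <= 1.0:
            raise ValueError("shadow_darkening must be in [0,1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 <= self.background_level <= 255:
            raise ValueError("background_level must be in [0,255]")


@dataclass
class LabeledSample:
    """One rendered fruit with its ground truth."""

    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) bool, True on fruit
    weight_g: float
    true_grade: int
    species_tag: str = "synthetic"
    spec: FruitSpec | None = None


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float], axes: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    # inclusive boundary: lattice points with normalized radius <= 1
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def ellipse_lattice_count(center: tuple[float, float], axes: tuple[float, float], shape: tuple[int, int]) -> int:
    """Number of integer lattice pixels inside the (inclusive) ellipse."""
    return int(_ellipse_mask(shape, center, axes).sum())


def render_fruit_image(spec: FruitSpec, rng_seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Render one scene; returns ``(image, mask)``.

    Before noise the image holds exactly three pixel populations —
    background, shadow crescent, fruit — or fewer when ``shadow_darkening``
    is zero.  Identical ``(spec, rng_seed)`` gives byte-identical output.
    """
    spec.validate()
    h, w = spec.image_size
    fruit = _ellipse_mask((h, w), spec.center, spec.axes)
    shadow_center = (spec.center[0] + spec.shadow_offset_px, spec.center[1])
    shadow = _ellipse_mask((h, w), shadow_center, spec.axes) & ~fruit

    img = np.empty((h, w, 3), dtype=np.float64)
    img[...] = spec.background_level
    img[shadow] = spec.background_level * (1.0 - spec.shadow_darkening)
    img[fruit] = np.asarray(spec.fruit_color, dtype=np.float64)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)

    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return img, fruit


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, low: float = 0.0) -> float:
    """Draw Normal(mean, sd) conditioned on being > low (rejection)."""
    if sd == 0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > low:
            return float(x)
    raise RuntimeError(f"truncated normal sampling failed for mean={mean}, sd={sd}")


def sample_grade_population(
    params: GradeParams,
    template: FruitSpec,
    n: int,
    rng_seed: int,
    species_tag: str = "synthetic",
) -> list[LabeledSample]:
    """Draw ``n`` labelled fruit from one grade's population.

    Fruit color is Normal(color_mean, color_sd) clipped to [0,255]; the
    ellipse radius (used for both semi-axes) and the weight are normal,
    truncated positive.  Per-sample render seeds are spawned from
    ``rng_seed`` so the population is reproducible as a whole.
    """
    if n < 1:
        raise ValueError(f"population size must be >= 1, got {n}")
    root = np.random.SeedSequence(rng_seed)
    param_rng = np.random.default_rng(root.spawn(1)[0])
    render_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n + 1)[1:]]

    samples: list[LabeledSample] = []
    for i in range(n):
        color = tuple(
            float(np.clip(param_rng.normal(m, s) if s > 0 else m, 0, 255))
            for m, s in zip(params.color_mean, params.color_sd)
        )
        radius = _truncated_normal(param_rng, params.radius_mean_px, params.radius_sd_px, low=1.0)
        weight = _truncated_normal(param_rng, params.weight_mean_g, params.weight_sd_g, low=0.0)
        spec = replace(template, axes=(radius, radius), fruit_color=color)
        image, mask = render_fruit_image(spec, render_seeds[i])
        samples.append(
            LabeledSample(
                image=image,
                mask=mask,
                weight_g=weight,
                true_grade=params.grade_index,
                species_tag=species_tag,
                spec=spec,
            )
        )
    return samples


def make_benchmark_dataset(
    grade_params: Sequence[GradeParams],
    template: FruitSpec,
    n_per_grade: int,
    rng_seed: int,
    out_dir: str | Path,
    species_tag: str = "synthetic",
) -> pd.DataFrame:
    """Write a labelled image dataset to ``out_dir`` and return its manifest.

    One PNG per fruit plus a 0/255 mask PNG, and ``manifest.csv`` with header
    ``filename,weight_g,true_grade,species``.  Regeneration with the same
    seed and parameters is byte-identical.
    """
    indices = [p.grade_index for p in grade_params]
    if sorted(indices) != [1, 2, 3, 4]:
        raise ValueError(f"need four GradeParams with distinct grade_index 1-4, got {indices}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    grade_seeds = np.random.SeedSequence(rng_seed).spawn(4)
    for params, seq in zip(sorted(grade_params, key=lambda p: p.grade_index), grade_seeds):
        seed = int(seq.generate_state(1)[0] % (2**31))
        for i, s in enumerate(sample_grade_population(params, template, n_per_grade, seed, species_tag)):
            stem = f"{species_tag}_g{params.grade_index}_{i:03d}"
            Image.fromarray(s.image).save(out / f"{stem}.png")
            Image.fromarray((s.mask.astype(np.uint8)) * 255).save(out / f"{stem}_mask.png")
            rows.append(
                {
                    "filename": f"{stem}.png",
                    "weight_g": round(s.weight_g, 3),
                    "true_grade": s.true_grade,
                    "species": species_tag,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def manifest_checksum(manifest_path: str | Path) -> str:
    """SHA-256 of a manifest file, for reproducibility checks."""
    return hashlib.sha256(Path(manifest_path).read_bytes()).hexdigest()


def available_presets() -> list[str]:
    return list(PRESET_SPECIES)


def load_preset(species: str) -> tuple[list[GradeParams], FruitSpec]:
    """Load a species preset (four grades + scene template) from package data."""
    if species not in PRESET_SPECIES:
        raise ValueError(f"unknown preset {species!r}; available: {', '.join(PRESET_SPECIES)}")
    text = resources.files("fruitgrade.data").joinpath(f"{species}.yaml").read_text()
    return parse_preset(yaml.safe_load(text))


def parse_preset(doc: dict) -> tuple[list[GradeParams], FruitSpec]:
    """Build (grade params, template) from a preset-format mapping."""
    t = doc.get("template", {})
    template = FruitSpec(
        image_size=tuple(t.get("image_size", (120, 160))),
        center=tuple(t.get("center", (60.0, 80.0))),
        axes=tuple(t.get("axes", (25.0, 25.0))),
        background_level=float(t.get("background_level", 235.0)),
        shadow_offset_px=int(t.get("shadow_offset_px", 6)),
        shadow_darkening=float(t.get("shadow_darkening", 0.08)),
        noise_sd=float(t.get("noise_sd", 4.0)),
    )
    grades = [
        GradeParams(
            grade_index=int(g["grade_index"]),
            color_mean=tuple(g["color_mean"]),
            color_sd=tuple(g.get("color_sd", (4.0, 4.0, 4.0))),
            radius_mean_px=float(g["radius_mean_px"]),
            radius_sd_px=float(g.get("radius_sd_px", 1.0)),
            weight_mean_g=float(g["weight_mean_g"]),
            weight_sd_g=float(g.get("weight_sd_g", 5.0)),
        )
        for g in doc["grades"]
    ]
    return grades, template


def sample_fruit_spec(rng: np.random.Generator, template: FruitSpec | None = None) -> FruitSpec:
    """Draw a random scene spec with a morphologically smooth ellipse.

    Semi-axes are sampled with fractional part in [0.25, 0.75]: discrete
    ellipses with near-integer semi-axes develop one-pixel tips at the ends
    of their axes, which a 3x3 morphological opening removes; keeping the
    axes off-integer makes the rendered boundary at least three pixels wide
    everywhere, so noise-free masks survive opening/closing unchanged.
    """
    template = template or FruitSpec()
    a = float(rng.integers(15, 34)) + float(rng.uniform(0.25, 0.75))
    b = float(rng.integers(15, 34)) + float(rng.uniform(0.25, 0.75))
    h, w = template.image_size
    cr = float(rng.integers(-6, 7)) + h / 2
    cc = float(rng.integers(-6, 7)) + w / 2
    return replace(template, center=(cr, cc), axes=(a, b))


def separation_preset(
    k_sd: float,
    color_sd: float = 6.0,
    radius_sd: float = 1.2,
    weight_sd: float = 6.0,
) -> tuple[list[GradeParams], FruitSpec]:
    """Four grades whose adjacent means sit exactly ``k_sd`` SDs apart.

    Used to study how grade-recovery accuracy depends on population
    separation: each of red channel, radius and weight steps down by
    ``k_sd`` times its own SD from grade to grade, anchored so the grade-1
    fruit resembles the peach preset.
    """
    grades = []
    for g in range(1, 5):
        step = (g - 1) * k_sd
        grades.append(
            GradeParams(
                grade_index=g,
                color_mean=(
                    min(235.0, 220.0 - step * color_sd),
                    min(235.0, 120.0 + 0.5 * step * color_sd),
                    90.0,
                ),
                color_sd=(color_sd, color_sd, color_sd),
                radius_mean_px=30.5 - step * radius_sd,
                radius_sd_px=radius_sd,
                weight_mean_g=180.0 - step * weight_sd,
                weight_sd_g=weight_sd,
            )
        )
    return grades, FruitSpec()
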