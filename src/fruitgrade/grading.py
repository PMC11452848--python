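"""Reference-statistics quality scoring and grade assignment.

Each grade keeps a reference profile estimated from a handful of training
fruit: per-feature mean x̄ = Σx_i/n and population variance
Var = Σ(x_i - x̄)²/n, with a [x̄ - Var, x̄ + Var] plausibility range.  A new
fruit is compared to a grade through normalized distances

    dR = sqrt( ((Rm-Rx)/Rv)² + ((Gm-Gx)/Gv)² + ((Bm-Bx)/Bv)² )
    dS = |Sm - Sx| / Sv          (size, pixels)
    dW = |Wm - Wx| / Wv          (weight, grams)

where the denominators are by default the per-grade standard deviations
(``scale_mode="std"``, so each term is a z-score; ``scale_mode="variance"``
divides by the raw variance instead).  The three distances combine into one
quality score

    Q = (e^{-dR} + e^{-dW} + e^{-dS}) / 3  in (0, 1],

equal weights for color, size and weight.  A fruit is assigned the grade
with the highest Q; the per-grade [Qmin, Qmax] band observed on training
data is recorded and reported as an in-range flag, not used to reject.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .color import FeatureVector

__all__ = [
    "EPS_SCALE",
    "FEATURE_KEYS",
    "GradeReference",
    "QualityResult",
    "fit_grade_reference",
    "feature_distances",
    "quality_score",
    "fit_q_ranges",
    "assign_grade",
    "fit_references",
    "save_references",
    "load_references",
]

#: floor for reference scales, prevents division by zero on constant features
EPS_SCALE = 1e-6

#: features entering the distance computation, in (color..., size, weight) order
FEATURE_KEYS = ("R", "G", "B", "size", "weight")


def _measured(fv: FeatureVector, color_mode: str) -> dict[str, float]:
    if color_mode == "mean_rgb":
        color = (fv.R_mean, fv.G_mean, fv.B_mean)
    elif color_mode == "chromaticity":
        color = (fv.r, fv.g, fv.b)
    else:
        raise ValueError(f"unknown color_mode {color_mode!r}")
    return dict(zip(FEATURE_KEYS, (*color, float(fv.size_px), fv.weight_g)))


@dataclass
class GradeReference:
    """Per-grade feature means, dispersions, ranges and observed Q band."""

    grade_index: int
    means: dict[str, float]
    scales: dict[str, float]
    variances: dict[str, float]
    range_min: dict[str, float]
    range_max: dict[str, float]
    n_samples: int
    scale_mode: str = "std"
    color_mode: str = "mean_rgb"
    q_min: float | None = None
    q_max: float | None = None


@dataclass
class QualityResult:
    """Distances and Q for every grade, plus the argmax-Q assignment."""

    distances: dict[int, tuple[float, float, float]]
    q: dict[int, float]
    assigned_grade: int
    in_range: dict[int, bool] = field(default_factory=dict)


def fit_grade_reference(
    samples: Sequence[FeatureVector],
    grade_index: int,
    scale_mode: str = "std",
    color_mode: str = "mean_rgb",
) -> GradeReference:
    """Estimate one grade's reference statistics from >= 2 training fruit.

    Mean and population variance (divisor n) per feature; the distance
    scale is sqrt(variance) for ``scale_mode="std"`` or the variance itself
    for ``"variance"``, floored at ``EPS_SCALE``; the plausibility range is
    mean ± variance.
    """
    if len(samples) < 2:
        raise ValueError(f"need at least 2 samples to fit a grade reference, got {len(samples)}")
    if scale_mode not in ("std", "variance"):
        raise ValueError(f"scale_mode must be 'std' or 'variance', got {scale_mode!r}")
    rows = [_measured(fv, color_mode) for fv in samples]
    means, scales, variances, rmin, rmax = {}, {}, {}, {}, {}
    for key in FEATURE_KEYS:
        x = np.array([row[key] for row in rows], dtype=np.float64)
        mu = float(x.mean())
        var = float(np.mean((x - mu) ** 2))
        means[key] = mu
        variances[key] = var
        scale = math.sqrt(var) if scale_mode == "std" else var
        scales[key] = max(scale, EPS_SCALE)
        rmin[key] = mu - var
        rmax[key] = mu + var
    return GradeReference(
        grade_index=grade_index,
        means=means,
        scales=scales,
        variances=variances,
        range_min=rmin,
        range_max=rmax,
        n_samples=len(samples),
        scale_mode=scale_mode,
        color_mode=color_mode,
    )


def feature_distances(measured: FeatureVector, ref: GradeReference) -> tuple[float, float, float]:
    """(dR, dS, dW): color is the 3-channel z-norm, size and weight 1-D."""
    m = _measured(measured, ref.color_mode)
    dR = math.sqrt(
        sum(((m[k] - ref.means[k]) / ref.scales[k]) ** 2 for k in ("R", "G", "B"))
    )
    dS = abs(m["size"] - ref.means["size"]) / ref.scales["size"]
    dW = abs(m["weight"] - ref.means["weight"]) / ref.scales["weight"]
    return dR, dS, dW


def quality_score(dR: float, dS: float, dW: float) -> float:
    """Q = (e^-dR + e^-dW + e^-dS)/3; 1 at a perfect match, -> 0 far away."""
    if dR < 0 or dS < 0 or dW < 0:
        raise ValueError(f"distances must be nonnegative, got ({dR}, {dS}, {dW})")
    return (math.exp(-dR) + math.exp(-dW) + math.exp(-dS)) / 3.0


def fit_q_ranges(
    references: dict[int, GradeReference],
    training: Iterable[tuple[FeatureVector, int]],
) -> dict[int, GradeReference]:
    """Record each grade's min/max Q over its own training samples."""
    per_grade: dict[int, list[float]] = {g: [] for g in references}
    for fv, grade in training:
        if grade not in references:
            raise ValueError(f"training sample labelled grade {grade} has no reference")
        per_grade[grade].append(quality_score(*feature_distances(fv, references[grade])))
    for g, qs in per_grade.items():
        if not qs:
            raise ValueError(f"grade {g} has no training samples for its Q range")
        references[g].q_min = min(qs)
        references[g].q_max = max(qs)
    return references


def assign_grade(measured: FeatureVector, references: dict[int, GradeReference]) -> QualityResult:
    """Score a fruit against all four grades and take the argmax of Q.

    Ties go to the lowest grade index.  When Q bands were fitted, each
    grade's flag records whether Q landed inside its training band.
    """
    if sorted(references) != [1, 2, 3, 4]:
        raise ValueError(f"references must cover grades 1-4, got {sorted(references)}")
    distances: dict[int, tuple[float, float, float]] = {}
    q: dict[int, float] = {}
    in_range: dict[int, bool] = {}
    for g in (1, 2, 3, 4):
        ref = references[g]
        d = feature_distances(measured, ref)
        distances[g] = d
        q[g] = quality_score(*d)
        if ref.q_min is not None and ref.q_max is not None:
            in_range[g] = ref.q_min <= q[g] <= ref.q_max
    assigned = max((1, 2, 3, 4), key=lambda g: (q[g], -g))
    return QualityResult(distances=distances, q=q, assigned_grade=assigned, in_range=in_range)


def fit_references(
    training: Sequence[tuple[FeatureVector, int]],
    scale_mode: str = "std",
    color_mode: str = "mean_rgb",
    n_reference: int | None = 10,
) -> dict[int, GradeReference]:
    """Fit all four grade references from labelled training fruit.

    Only the first ``n_reference`` samples of each grade enter the
    mean/variance estimate (pass None to use all), mirroring a calibration
    run with a small number of hand-graded reference fruit; Q bands are
    then fitted on the full training set.
    """
    refs: dict[int, GradeReference] = {}
    for g in (1, 2, 3, 4):
        fvs = [fv for fv, grade in training if grade == g]
        if n_reference is not None:
            fvs = fvs[:n_reference]
        refs[g] = fit_grade_reference(fvs, g, scale_mode=scale_mode, color_mode=color_mode)
    return fit_q_ranges(refs, training)


def save_references(references: dict[int, GradeReference], path: str | Path) -> None:
    doc = {
        str(g): {
            "grade_index": r.grade_index,
            "means": r.means,
            "scales": r.scales,
            "variances": r.variances,
            "range_min": r.range_min,
            "range_max": r.range_max,
            "n_samples": r.n_samples,
            "scale_mode": r.scale_mode,
            "color_mode": r.color_mode,
            "q_min": r.q_min,
            "q_max": r.q_max,
        }
        for g, r in references.items()
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_references(path: str | Path) -> dict[int, GradeReference]:
    doc = json.loads(Path(path).read_text())
    return {int(g): GradeReference(**r) for g, r in doc.items()}
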