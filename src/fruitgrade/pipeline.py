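"""End-to-end grading runs: dataset in, features, grades and reports out.

Ties the stages together the way the sorting line uses them: read a dataset
manifest, segment each image, measure color/size/weight features, fit the
per-grade references on a training split, grade the held-out fruit with
both the Q-score rule and the MLP, and write everything as plain-text
artifacts (CSV/JSON) plus a run manifest that pins config, seed and library
versions so a rerun is bit-identical.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import classify, grading, segment
from .classify import MLPConfig
from .color import ColorSampleConfig, FeatureVector, extract_features
from .segment import ThresholdConfig

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config", "save_config"]

log = logging.getLogger("fruitgrade")


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of an end-to-end run; defaults match the sorting rig's
    operating point (15 color points, gray band 0-185, 10 reference fruit)."""

    n_points: int = 15
    upper: int = 185
    lower: int = 0
    use_otsu: bool = False
    n_reference: int = 10
    scale_mode: str = "std"
    color_mode: str = "mean_rgb"
    test_fraction: float = 0.5
    mlp: MLPConfig = field(default_factory=MLPConfig)
    rng_seed: int = 0
    species: str = "peach"

    def validate(self) -> None:
        ColorSampleConfig(n_points=self.n_points)  # raises outside [5,25]
        ThresholdConfig(upper=self.upper, lower=self.lower, use_otsu=self.use_otsu)
        if self.n_reference < 2:
            raise ValueError("n_reference must be >= 2")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0,1)")
        if self.scale_mode not in ("std", "variance"):
            raise ValueError(f"scale_mode must be 'std' or 'variance', got {self.scale_mode!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mlp"]["hidden_sizes"] = list(self.mlp.hidden_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        mlp = d.pop("mlp", {})
        if "hidden_sizes" in mlp:
            mlp["hidden_sizes"] = tuple(mlp["hidden_sizes"])
        return cls(mlp=MLPConfig(**mlp), **d)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    """In-memory view of one run's outputs."""

    features: pd.DataFrame
    references: dict[int, grading.GradeReference]
    grading: pd.DataFrame
    q_confusion: classify.ConfusionMatrix
    mlp_confusion: classify.ConfusionMatrix
    q_accuracy: float
    mlp_accuracy: float
    rejects: list[str]


def _sample_seed(root: np.random.SeedSequence, index: int) -> int:
    return int(np.random.SeedSequence(entropy=root.entropy, spawn_key=(index,)).generate_state(1)[0] % (2**31))


def run_pipeline(dataset_dir: str | Path, out_dir: str | Path, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full grading flow on a dataset directory with a manifest.

    Writes features.csv, references.json, grading.csv, confusion/report
    files for both graders, rejects.csv and run_manifest.json into
    ``out_dir``.  Corrupt images are skipped with a logged warning.
    """
    config = config or PipelineConfig()
    config.validate()
    dataset_dir = Path(dataset_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest_path = dataset_dir / "manifest.csv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.csv in {dataset_dir}")
    manifest = pd.read_csv(manifest_path)
    log.info("run: %d samples from %s", len(manifest), dataset_dir)

    tconf = ThresholdConfig(upper=config.upper, lower=config.lower, use_otsu=config.use_otsu)
    root = np.random.SeedSequence(config.rng_seed)

    fvs: list[FeatureVector] = []
    labels: list[int] = []
    ids: list[str] = []
    rejects: list[str] = []
    for i, row in manifest.iterrows():
        fname = str(row["filename"])
        try:
            image = np.asarray(Image.open(dataset_dir / fname).convert("RGB"))
            mask = segment.segment_fruit(image, tconf)
            fv = extract_features(
                image,
                mask,
                weight_g=float(row["weight_g"]),
                config=ColorSampleConfig(n_points=config.n_points, rng_seed=_sample_seed(root, int(i))),
            )
        except (OSError, ValueError) as exc:
            log.warning("rejected %s: %s", fname, exc)
            rejects.append(fname)
            continue
        fvs.append(fv)
        labels.append(int(row["true_grade"]))
        ids.append(fname)

    pd.DataFrame({"filename": rejects}).to_csv(out / "rejects.csv", index=False)
    if not fvs:
        raise ValueError(f"no usable samples in {dataset_dir}")

    feat_df = pd.DataFrame([fv.as_row() for fv in fvs])
    feat_df.insert(0, "sample_id", ids)
    feat_df["true_grade"] = labels
    feat_df.to_csv(out / "features.csv", index=False)

    train_idx, test_idx = classify.train_test_split_stratified(
        labels, test_fraction=config.test_fraction, rng_seed=config.rng_seed
    )
    log.info("split: %d train / %d test", train_idx.size, test_idx.size)

    training = [(fvs[i], labels[i]) for i in train_idx]
    refs = grading.fit_references(
        training,
        scale_mode=config.scale_mode,
        color_mode=config.color_mode,
        n_reference=config.n_reference,
    )
    grading.save_references(refs, out / "references.json")

    rows = []
    q_pred = []
    for i in test_idx:
        res = grading.assign_grade(fvs[i], refs)
        dR, dS, dW = res.distances[res.assigned_grade]
        rows.append(
            {
                "sample_id": ids[i],
                "dR": dR, "dS": dS, "dW": dW,
                "Q1": res.q[1], "Q2": res.q[2], "Q3": res.q[3], "Q4": res.q[4],
                "assigned_grade": res.assigned_grade,
                "true_grade": labels[i],
            }
        )
        q_pred.append(res.assigned_grade)
    grading_df = pd.DataFrame(rows)
    grading_df.to_csv(out / "grading.csv", index=False)

    X_train, T_train, scaler = classify.build_vectors([fvs[i] for i in train_idx], [labels[i] for i in train_idx])
    model = classify.train_mlp(X_train, T_train, config.mlp)
    model.scaler = scaler
    model.save(out / "mlp_model.json")
    X_test = scaler.transform(classify.feature_matrix([fvs[i] for i in test_idx]))
    mlp_pred = classify.predict_mlp(model, X_test)

    true_test = [labels[i] for i in test_idx]
    q_cm = classify.confusion_matrix(true_test, q_pred)
    mlp_cm = classify.confusion_matrix(true_test, mlp_pred)
    q_cm.to_csv(out / "confusion_qscore.csv")
    mlp_cm.to_csv(out / "confusion_mlp.csv")
    for name, cm in (("qscore", q_cm), ("mlp", mlp_cm)):
        classify.evaluation_report(cm).to_csv(out / f"report_{name}.csv", index=False)
        (out / f"report_{name}.txt").write_text(classify.report_text(cm) + "\n")

    q_acc = classify.overall_accuracy(q_cm)
    mlp_acc = classify.overall_accuracy(mlp_cm)
    log.info("test accuracy: q-score %.2f%%, mlp %.2f%%", q_acc, mlp_acc)

    run_manifest = {
        "config": config.to_dict(),
        "dataset": str(dataset_dir),
        "n_samples": len(fvs),
        "n_rejects": len(rejects),
        "versions": _versions(),
    }
    (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        features=feat_df,
        references=refs,
        grading=grading_df,
        q_confusion=q_cm,
        mlp_confusion=mlp_cm,
        q_accuracy=q_acc,
        mlp_accuracy=mlp_acc,
        rejects=rejects,
    )


def _versions() -> dict[str, str]:
    import sklearn
    import scipy
    import PIL

    return {
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "pillow": PIL.__version__,
    }
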