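"""End-to-end orchestration: segment -> correct -> filter -> classify.

Implements the pixel-dataset construction protocol (per-class random draws
from foreground pixels, 9:1 train:test by default), an SVM pixel classifier
(delegated to scikit-learn), evaluation statistics (confusion matrix,
accuracies, Cohen's kappa), and a config-driven runner whose comparative
mode trains the same classifier on unfiltered, SG-filtered and TSG-filtered
versions of one corrected scene.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from hsiprep import correction, phantom, quality, segmentation, sgfilter
from hsiprep.cube_io import (BinaryMask, HyperCube, ValidationError, crop,
                             write_cube, write_mask)

__all__ = [
    "PixelDataset",
    "EvalResult",
    "ModelHandle",
    "cohen_kappa",
    "build_pixel_dataset",
    "train_classifier",
    "evaluate",
    "save_model",
    "load_model",
    "default_config",
    "run_pipeline",
]


@dataclass
class PixelDataset:
    """Per-pixel spectra with labels, a train/test split and provenance."""

    features: np.ndarray        # (n_samples, n_features)
    labels: np.ndarray          # (n_samples,) int class indices
    split: np.ndarray           # (n_samples,) "train" / "test"
    provenance: np.ndarray      # (n_samples, 3) = (cube_id, x, y)
    feature_mode: str
    rng_seed: int
    class_names: tuple[str, ...] = phantom.CLASS_NAMES

    def __post_init__(self) -> None:
        n = len(self.features)
        if not (len(self.labels) == len(self.split) == len(self.provenance) == n):
            raise ValidationError("dataset arrays disagree in length")
        keys = {tuple(row) for row in self.provenance}
        if len(keys) != n:
            raise ValidationError("a (cube, x, y) sample appears twice")

    def subset(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        sel = self.split == which
        return self.features[sel], self.labels[sel]


@dataclass
class EvalResult:
    """Classification scores in the two-accuracy-columns-plus-kappa shape."""

    confusion: np.ndarray        # class x class counts on the test split
    test_accuracy: float
    total_accuracy: float        # pooled train+test predictions
    kappa: float

    def as_dict(self) -> dict[str, float]:
        return {
            "test_accuracy": self.test_accuracy,
            "total_accuracy": self.total_accuracy,
            "kappa": self.kappa,
        }


@dataclass
class ModelHandle:
    """A trained classifier plus the feature convention it expects."""

    model: SVC
    feature_mode: str
    n_features: int

    def predict(self, features: np.ndarray) -> np.ndarray:
        if features.shape[1] != self.n_features:
            raise ValidationError(
                f"model expects {self.n_features} features, got {features.shape[1]}"
            )
        return self.model.predict(features)


def cohen_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e) from a confusion
    matrix; 1.0 for perfect agreement even when p_e = 1."""
    confusion = np.asarray(confusion, dtype=float)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValidationError("confusion matrix must be square")
    n = confusion.sum()
    if n == 0:
        raise ValidationError("empty confusion matrix")
    p_o = np.trace(confusion) / n
    p_e = float(np.sum(confusion.sum(axis=0) * confusion.sum(axis=1))) / (n * n)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def _parse_feature_mode(mode: str) -> int | None:
    if mode == "raw":
        return None
    if mode.startswith("pca-"):
        k = int(mode[4:])
        if k < 1:
            raise ValidationError(f"invalid feature mode {mode!r}")
        return k
    raise ValidationError(f"unknown feature mode {mode!r} (use 'raw' or 'pca-<k>')")


def build_pixel_dataset(sources: Sequence[tuple[HyperCube, np.ndarray]],
                        n_train: int, n_test: int,
                        feature_mode: str = "raw",
                        rng_seed: int = 0) -> PixelDataset:
    """Draw labeled pixel spectra from one or more cubes.

    ``sources`` pairs each cube with a per-pixel label map (int class index,
    -1 = background/unlabeled).  ``n_train`` + ``n_test`` samples are drawn
    without replacement *per cube per class*, so a 9:1 ratio holds exactly
    per class.  ``feature_mode="pca-k"`` projects spectra onto the first k
    principal components fitted on the training samples only.
    """
    if n_train < 1 or n_test < 0:
        raise ValidationError("need n_train >= 1 and n_test >= 0")
    k = _parse_feature_mode(feature_mode)
    rng = np.random.default_rng(rng_seed)
    feats, labels, split, prov = [], [], [], []
    for cube_id, (cube, label_map) in enumerate(sources):
        label_map = np.asarray(label_map)
        if label_map.shape != cube.shape[:2]:
            raise ValidationError(
                f"label map shape {label_map.shape} does not match cube {cube.shape[:2]}"
            )
        for cls in np.unique(label_map[label_map >= 0]):
            xs, ys = np.nonzero(label_map == cls)
            if len(xs) < n_train + n_test:
                raise ValidationError(
                    f"class {cls} in cube {cube_id} has {len(xs)} labeled pixels, "
                    f"need {n_train + n_test}"
                )
            pick = rng.choice(len(xs), size=n_train + n_test, replace=False)
            for rank, j in enumerate(pick):
                feats.append(cube.data[xs[j], ys[j], :].astype(float))
                labels.append(int(cls))
                split.append("train" if rank < n_train else "test")
                prov.append((cube_id, int(xs[j]), int(ys[j])))
    features = np.asarray(feats)
    split_arr = np.asarray(split)
    if k is not None:
        if k > features.shape[1]:
            raise ValidationError(f"pca-{k} exceeds feature length {features.shape[1]}")
        pca = PCA(n_components=k, svd_solver="full")
        pca.fit(features[split_arr == "train"])
        features = pca.transform(features)
    return PixelDataset(features, np.asarray(labels), split_arr,
                        np.asarray(prov), feature_mode, rng_seed)


def train_classifier(dataset: PixelDataset,
                     params: Mapping[str, Any] | None = None) -> ModelHandle:
    """Fit an RBF-kernel SVM on the training split.

    Defaults: C=1, gamma scaled by feature variance.  Training is
    deterministic for a fixed dataset.
    """
    x_train, y_train = dataset.subset("train")
    if len(np.unique(y_train)) < 2:
        raise ValidationError("training split holds a single class")
    opts: dict[str, Any] = {"kernel": "rbf", "C": 1.0, "gamma": "scale"}
    opts.update(params or {})
    model = SVC(**opts)
    model.fit(x_train, y_train)
    return ModelHandle(model, dataset.feature_mode, x_train.shape[1])


def evaluate(model: ModelHandle, dataset: PixelDataset) -> EvalResult:
    """Score a model: test confusion/accuracy/kappa plus pooled accuracy.

    "Total" accuracy pools the train and test predictions, mirroring the
    two-accuracy-column reporting convention; kappa comes from the test
    confusion matrix.
    """
    if model.feature_mode != dataset.feature_mode:
        raise ValidationError(
            f"model was trained with features {model.feature_mode!r}, "
            f"dataset provides {dataset.feature_mode!r}"
        )
    x_test, y_test = dataset.subset("test")
    pred_test = model.predict(x_test)
    classes = np.unique(dataset.labels)
    lut = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_test, pred_test):
        confusion[lut[t], lut[p]] += 1
    pred_all = model.predict(dataset.features)
    return EvalResult(
        confusion=confusion,
        test_accuracy=float(np.mean(pred_test == y_test)),
        total_accuracy=float(np.mean(pred_all == dataset.labels)),
        kappa=cohen_kappa(confusion),
    )


def save_model(handle: ModelHandle, path: str | Path) -> None:
    import joblib

    joblib.dump(handle, path)


def load_model(path: str | Path) -> ModelHandle:
    import joblib

    return joblib.load(path)


# ---------------------------------------------------------------------------
# Config-driven runner
# ---------------------------------------------------------------------------

def default_config(seed: int = 0) -> dict[str, Any]:
    """The reference pipeline configuration (all seeds explicit)."""
    return {
        "seed": seed,
        "scene": {},                      # SceneSpec field overrides
        "segmentation": {},               # SegmentParams field overrides
        "sg": {"m": 7, "n": 3},
        "tsg": {"m": 3, "n": 4},
        "variants": ["none", "sg", "tsg"],
        "dataset": {"n_train": 720, "n_test": 80, "feature_mode": "pca-6"},
        "svm": {},
        "mse_window_nm": [500.0, 900.0],
    }


def correct_scene(cube: HyperCube, spec: phantom.SceneSpec) -> tuple[HyperCube, correction.NoiseField]:
    """Double-plate correction of a rendered scene using its 2%/98% plates."""
    ny = spec.ny
    regions = {
        refl: correction.PlateRegion(refl, spec.plate_x_interval(refl), (0, ny))
        for refl in (0.02, 0.98)
    }
    p_low = correction.plate_profile(cube, regions[0.02])
    p_high = correction.plate_profile(cube, regions[0.98])
    noise = correction.estimate_noise(p_low, p_high)
    g = correction.subtract_noise(cube, noise)
    g_high = correction.PlateProfile(p_high.values - noise.values, regions[0.98])
    return correction.reflectance_invert(g, g_high), noise


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path) -> Path:
    """Run simulate -> correct -> segment -> filter variants -> classify.

    Writes stage artifacts (corrected cube, mask, per-variant quality
    reports, comparative summary) plus ``manifest.json`` recording every
    parameter, seed and output hash.  Identical configs produce identical
    manifests.
    """
    cfg = default_config()
    for key, value in config.items():
        if isinstance(value, Mapping) and isinstance(cfg.get(key), dict):
            cfg[key] = {**cfg[key], **value}
        else:
            cfg[key] = value
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    spec = phantom.SceneSpec(rng_seed=int(cfg["seed"]), **cfg["scene"])
    dn_cube, truth = phantom.render_scene(spec)

    corrected, noise = correct_scene(dn_cube, spec)

    # 50%-plate self-check: corrected spectrum vs the known 0.50 truth
    x0, x1 = spec.plate_x_interval(0.50)
    target_mean = corrected.data[x0:x1, :, :].mean(axis=(0, 1))
    _, mse = correction.correction_mse(
        target_mean, np.full(spec.n_bands, 0.50), corrected.wavelengths,
        tuple(cfg["mse_window_nm"]))

    # work on the sample region only (plates cropped away, as for real scenes)
    s0, s1 = spec.sample_x_interval
    sample = crop(corrected, x_range=(s0, s1))
    label_map = truth.label_map[s0:s1, :]

    seg_params = segmentation.SegmentParams(**cfg["segmentation"])
    mask, seg_diag = segmentation.segment_pipeline(sample, seg_params)
    write_mask(mask, out / "mask.png")
    write_cube(sample, out / "corrected.npz")

    rows = []
    reports: dict[str, Any] = {}
    for variant in cfg["variants"]:
        if variant == "none":
            filtered = sample
            report = quality.quality_report(sample)
        elif variant == "sg":
            filtered = sgfilter.sg_filter_spectra(sample, **cfg["sg"])
            report = quality.quality_report(sample, filtered)
        elif variant == "tsg":
            filtered = sgfilter.tsg_filter(sample, **cfg["tsg"])
            report = quality.quality_report(sample, filtered)
        else:
            raise ValidationError(f"unknown variant {variant!r}")
        report.to_csv(out / f"quality_{variant}.csv")
        reports[variant] = report

        masked_labels = np.where(mask.grid, label_map, -1)
        dataset = build_pixel_dataset(
            [(filtered, masked_labels)],
            rng_seed=int(cfg["seed"]) + 1, **cfg["dataset"])
        handle = train_classifier(dataset, cfg["svm"])
        result = evaluate(handle, dataset)
        rows.append({"filtering": variant, **result.as_dict()})

    summary = pd.DataFrame(rows)
    summary.to_csv(out / "summary.csv", index=False)

    manifest = {
        "config": cfg,
        "scene": {"extents": [spec.nx, spec.ny, spec.n_bands],
                  "foreground_pixels": truth.foreground_mask.count},
        "correction_mse_50pct_plate": mse,
        "segmentation": seg_diag,
        "summary": rows,
        "outputs": {p.name: _sha256(p) for p in sorted(out.iterdir())
                    if p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
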