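"""File I/O, run configuration and the end-to-end pipeline.

Conventions (chosen for diff-ability in tests): grayscale images as 8- or
16-bit PNG/TIFF, masks as 0/255 8-bit PNG, contours as CSV with header
``x,y`` (float pixels, 0-based), feature tables and predictions as CSV with
header, metrics as JSON, models via joblib with the normalizer and (c, g)
embedded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, fields as dc_fields
from pathlib import Path

import imageio.v3 as iio
import joblib
import numpy as np
import pandas as pd
import yaml

from .classify import (SVMConfig, TrainedModel, confusion, cross_validate_grid,
                       fit_normalizer, metrics, roc_auc, train_svm)
from .features import CharacteristicFeatures, FeatureConfig, characteristic_features
from .phantom import PhantomSpec, benign_spec, generate_phantom, malignant_spec
from .segmentation import DRLSEParams, segment_lesion

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig", "load_image", "save_image", "save_mask",
    "read_contour", "write_contour", "save_model", "load_model",
    "run_pipeline",
]

_LUMA = np.array([0.2126, 0.7152, 0.0722])


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF as a [0, 1] float grayscale array.

    Integer images are scaled by their dtype maximum; RGB(A) input is
    collapsed to luminance.  The original dtype and shape are logged.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if raw.size == 0:
        raise IOError(f"empty image {path}")
    logger.info("loaded %s: shape=%s dtype=%s", path, raw.shape, raw.dtype)
    arr = np.asarray(raw)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
        scale = np.iinfo(raw.dtype).max if np.issubdtype(raw.dtype, np.integer) else 1.0
        return np.clip(arr / scale, 0.0, 1.0)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / np.iinfo(arr.dtype).max
    return np.clip(arr.astype(float), 0.0, 1.0)


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit PNG/TIFF."""
    out = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), (out * 255).round().astype(np.uint8))


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def load_mask(path: str | Path) -> np.ndarray:
    return load_image(path) > 0.5


def write_contour(path: str | Path, contour: np.ndarray) -> None:
    pd.DataFrame(np.asarray(contour, dtype=float), columns=["x", "y"]).to_csv(
        path, index=False)


def read_contour(path: str | Path) -> np.ndarray:
    """Read an ``x,y`` CSV contour; malformed rows error with their line."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise IOError(f"empty contour file {path}") from exc
    if list(df.columns) != ["x", "y"]:
        raise IOError(f"{path}: expected header 'x,y', got {list(df.columns)}")
    for col in ("x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(coerced.isna().to_numpy())[0]
        if bad.size:
            # +2: one for the header line, one for 1-based numbering
            raise IOError(f"{path}: non-numeric value in column {col} "
                          f"at line {bad[0] + 2}")
    return df.to_numpy(dtype=float)


def save_model(path: str | Path, model: TrainedModel) -> None:
    joblib.dump(model, path)


def load_model(path: str | Path) -> TrainedModel:
    model = joblib.load(path)
    if not isinstance(model, TrainedModel):
        raise IOError(f"{path} does not contain a trained model")
    return model


def read_dlf(path: str | Path) -> pd.DataFrame:
    """Deep-feature CSV: first column ``image`` (key), remaining columns DLF."""
    df = pd.read_csv(path)
    if df.columns[0] != "image":
        raise IOError(f"{path}: first column must be 'image'")
    return df.set_index("image")


# ----------------------------------------------------------------- config

def _from_mapping(cls, data: dict, context: str):
    allowed = {f.name for f in dc_fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {context} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs, parseable from a single YAML file.

    Unknown keys are rejected so a typo cannot silently fall back to a
    default.  All randomness flows from the seeds recorded here.
    """

    segmentation: DRLSEParams = field(default_factory=DRLSEParams)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    svm: SVMConfig = field(default_factory=SVMConfig)
    seed: int = 0
    n_benign: int = 20
    n_malignant: int = 20
    test_fraction: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        data = dict(data)
        seg = _from_mapping(DRLSEParams, data.pop("segmentation", {}), "segmentation")
        feat_raw = dict(data.pop("features", {}))
        if "radii" in feat_raw:
            feat_raw["radii"] = tuple(feat_raw["radii"])
        feat = _from_mapping(FeatureConfig, feat_raw, "features")
        svm_raw = dict(data.pop("svm", {}))
        for key in ("c_grid", "g_grid"):
            if key in svm_raw:
                svm_raw[key] = tuple(svm_raw[key])
        svm = _from_mapping(SVMConfig, svm_raw, "svm")
        cfg = _from_mapping(
            cls, {**data, "segmentation": seg, "features": feat, "svm": svm}, "run")
        logger.info("resolved config: %s", asdict(cfg))
        return cfg


# --------------------------------------------------------------- pipeline

def _seed_from_mask(mask: np.ndarray, half: int = 6) -> tuple[int, int, int, int]:
    """Small seed rectangle around the mask centroid (x0, y0, x1, y1)."""
    rr, cc = np.nonzero(mask)
    cy, cx = int(rr.mean()), int(cc.mean())
    return (cx - half, cy - half, cx + half, cy + half)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None,
                 use_true_contours: bool = False) -> dict:
    """Phantom cohort end to end: generate, segment, score, train, evaluate.

    Generates ``n_benign`` benign-like and ``n_malignant`` malignant-like
    phantoms, segments each with DRLSE (or takes the ground-truth contour
    when ``use_true_contours``), computes the CF table, splits the cohort
    into train/test stratified by label, grid-searches the SVM on the
    training half and evaluates on the held-out half.

    Returns a dict with the feature ``table`` (DataFrame), the chosen
    ``(c, g)``, the trained model and the held-out ``metrics``.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for label, n, maker in ((0, config.n_benign, benign_spec),
                            (1, config.n_malignant, malignant_spec)):
        for i in range(n):
            spec = maker(int(rng.integers(0, 2**31 - 1)))
            image, mask, true_contour = generate_phantom(spec)
            name = f"{'benign' if label == 0 else 'malignant'}_{i:03d}"
            if use_true_contours:
                contour = true_contour
            else:
                try:
                    contour, _, _ = segment_lesion(
                        image, _seed_from_mask(mask), config.segmentation)
                except Exception as exc:
                    raise RuntimeError(
                        f"pipeline failed at segmentation of {name}: {exc}"
                    ) from exc
            try:
                cf = characteristic_features(image, contour, config.features)
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline failed at features of {name}: {exc}") from exc
            rows.append({"image": name, "label": label,
                         **dict(zip(CharacteristicFeatures.NAMES, cf.as_array()))})
    table = pd.DataFrame(rows)

    x = table[list(CharacteristicFeatures.NAMES)].to_numpy(float)
    y = table["label"].to_numpy(int)
    # stratified train/test split driven by the run seed
    split_rng = np.random.default_rng(config.seed + 1)
    test_idx = []
    for cls in (0, 1):
        idx = np.nonzero(y == cls)[0]
        k = max(int(round(len(idx) * config.test_fraction)), 1)
        test_idx.extend(split_rng.choice(idx, size=k, replace=False))
    is_test = np.zeros(len(y), bool)
    is_test[np.asarray(test_idx)] = True

    norm = fit_normalizer(x[~is_test], CharacteristicFeatures.NAMES)
    from .classify import apply_normalizer  # local to avoid cycle at import
    xn_train = apply_normalizer(norm, x[~is_test])
    best_c, best_g, surface = cross_validate_grid(xn_train, y[~is_test], config.svm)
    model = train_svm(x[~is_test], y[~is_test], best_c, best_g, normalizer=norm)

    pred = model.predict(x[is_test])
    scores = model.decision_scores(x[is_test])
    tp, fp, fn, tn = confusion(pred, y[is_test])
    evalm = metrics(tp, fp, fn, tn)
    _, auc = roc_auc(scores, y[is_test])
    result_metrics = {**evalm.to_dict(), "auc": auc}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "features.csv", index=False)
        save_model(out / "model.bin", model)
        with open(out / "metrics.json", "w") as fh:
            json.dump(result_metrics, fh, indent=2)

    return {"table": table, "c": best_c, "g": best_g, "surface": surface,
            "model": model, "metrics": result_metrics, "is_test": is_test}
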