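"""File I/O, pipeline configuration and the two end-to-end workflows.

Images travel as grayscale TIFF (single-page 2D, multi-page stacks), tables
as CSV with fixed headers, trained models as joblib files.  The pipeline
configuration is a strict YAML document (unknown keys are rejected, parse →
serialize → parse is lossless) and every pipeline stage logs its parameters
so any output can be reproduced from its log.

Coordinate convention: row-major, 0-based, (z, y, x) axis order for stacks;
a physical scale in µm always travels with pixel data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import classify, descriptors, quantify, segment, synthgen
from .preprocess import Image2D, PreprocessConfig, preprocess_pipeline

logger = logging.getLogger("mitomorph")

FLOAT_FORMAT = "%.9g"


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def read_image_tiff(path, pixel_size_um: float | None = None):
    """Read a grayscale TIFF.

    Returns an :class:`Image2D` for single-plane files and a (z, y, x)
    ``ndarray`` for multi-page stacks.  The physical scale comes from the
    TIFF resolution tags when present; an explicit ``pixel_size_um``
    overrides it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise ValueError(
                f"{path} is not single-channel grayscale "
                f"(samples per pixel = {page.samplesperpixel})"
            )
        data = tif.asarray()
        scale = pixel_size_um
        if scale is None:
            res = page.tags.get("XResolution")
            if res is not None:
                num, den = res.value
                if num > 0:
                    scale = den / num
    if data.ndim == 2:
        return Image2D(data, scale if scale else 1.0)
    return data


def write_image_tiff(path, data, pixel_size_um: float | None = None) -> None:
    """Write an array (or Image2D) as TIFF, embedding the scale when known."""
    if isinstance(data, Image2D):
        pixel_size_um = data.pixel_size_um
        data = data.pixels
    kwargs = {}
    if pixel_size_um:
        kwargs["resolution"] = (1.0 / pixel_size_um, 1.0 / pixel_size_um)
    tifffile.imwrite(path, np.asarray(data), **kwargs)


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def write_table_csv(table: pd.DataFrame, path) -> None:
    """Write a table with a header row; floats at 9 significant digits."""
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_table_csv(path, required_columns=None) -> pd.DataFrame:
    """Read a CSV table; column order is normalized by header names."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such table: {path}")
    df = pd.read_csv(path)
    if required_columns is not None:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise ValueError(f"table {path} is missing columns: {missing}")
        extras = [c for c in df.columns if c not in required_columns]
        df = df[list(required_columns) + extras]
    return df


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------

MODEL_FORMAT_VERSION = 1


def save_model(model: classify.TrainedClassifier, path) -> None:
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path) -> classify.TrainedClassifier:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model file version in {path}")
    return payload["model"]


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class SegmentationConfig:
    method: str = "pixelclassifier"  # or "otsu" / "fixed"
    fixed_level: float | None = None
    n_annotations_per_class: int = 1500
    min_area_um2: float = 0.30
    min_volume_um3: float = 0.02
    erode_iterations: int = 1
    connectivity: int = 6
    em_downsample_factor: int = 5


@dataclass
class ClassifierConfig:
    n_trees: int = 500
    n_repetitions: int = 25
    train_n_per_class: int = 100
    train_fraction: float = 0.8


@dataclass
class PipelineConfig:
    """Everything needed to run a 2D or 3D workflow end to end."""

    mode: str = "2d"  # "2d", "3d-confocal" or "3d-em"
    seed: int = 0
    n_images: int = 3
    synth: dict = field(default_factory=dict)  # SynthSpec field overrides
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def validate(self) -> None:
        if self.mode not in ("2d", "3d-confocal", "3d-em"):
            raise ValueError("mode must be '2d', '3d-confocal' or '3d-em'")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        self.preprocess.validate()


def _dataclass_from_dict(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def config_to_dict(cfg: PipelineConfig) -> dict:
    return {
        "mode": cfg.mode,
        "seed": cfg.seed,
        "n_images": cfg.n_images,
        "synth": dict(cfg.synth),
        "preprocess": dataclasses.asdict(cfg.preprocess),
        "segmentation": dataclasses.asdict(cfg.segmentation),
        "classifier": dataclasses.asdict(cfg.classifier),
    }


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data)
    unknown = set(data) - {
        "mode", "seed", "n_images", "synth", "preprocess", "segmentation",
        "classifier",
    }
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(
        mode=data.get("mode", "2d"),
        seed=int(data.get("seed", 0)),
        n_images=int(data.get("n_images", 3)),
        synth=dict(data.get("synth", {})),
        preprocess=_dataclass_from_dict(PreprocessConfig, data.get("preprocess", {})),
        segmentation=_dataclass_from_dict(
            SegmentationConfig, data.get("segmentation", {})
        ),
        classifier=_dataclass_from_dict(ClassifierConfig, data.get("classifier", {})),
    )
    cfg.validate()
    return cfg


def save_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))


def load_config(path) -> PipelineConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# End-to-end workflows
# ---------------------------------------------------------------------------

def _log_stage(name: str, t0: float, **params) -> None:
    logger.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - t0,
                json.dumps(params, default=str, sort_keys=True))


def _make_synth_spec(cfg: PipelineConfig, seed: int, three_d: bool):
    fields = dict(cfg.synth)
    fields["seed"] = seed
    if three_d:
        fields.setdefault("modality", "em" if cfg.mode == "3d-em" else "confocal")
        for key in ("image_shape", "voxel_size_um"):
            if key in fields:
                fields[key] = tuple(fields[key])
        return _dataclass_from_dict(synthgen.SynthSpec3D, fields)
    if "image_shape" in fields:
        fields["image_shape"] = tuple(fields["image_shape"])
    return _dataclass_from_dict(synthgen.SynthSpec2D, fields)


def _train_from_spec(cfg: PipelineConfig, spec, out: Path):
    """Train the morphology classifier on a clean generated object table."""
    t0 = time.perf_counter()
    train_spec = dataclasses.replace(
        spec, n_per_class=cfg.classifier.train_n_per_class, seed=spec.seed + 50_000
    )
    table = synthgen.sample_object_table(train_spec)
    train, test = classify.split_train_test(
        table, cfg.classifier.train_fraction, seed=spec.seed + 1
    )
    model = classify.train_random_forest(
        train,
        n_trees=cfg.classifier.n_trees,
        n_repetitions=cfg.classifier.n_repetitions,
        seed=spec.seed + 2,
    )
    cm, test_acc = classify.evaluate(model, test)
    save_model(model, out / "model.joblib")
    write_table_csv(cm.to_frame().reset_index(names="true_class"),
                    out / "confusion_matrix.csv")
    _log_stage("train", t0, n_train=len(train), n_test=len(test),
               training_accuracy=model.training_accuracy, test_accuracy=test_acc,
               max_features=model.chosen_max_features, seed=spec.seed)
    return model, test_acc


def _sample_annotations(truth_fg: np.ndarray, rng, n_per_class: int) -> np.ndarray:
    """Sparse tri-state annotation mask sampled from a ground-truth support.

    Plays the role of the hand-drawn mito/background scribbles that train
    the pixel classifier on real data.
    """
    ann = np.zeros(truth_fg.shape, dtype=np.uint8)
    for value, idx in ((segment.ANNOT_MITO, np.argwhere(truth_fg)),
                       (segment.ANNOT_BACKGROUND, np.argwhere(~truth_fg))):
        if len(idx) == 0:
            raise ValueError("ground truth lacks one annotation class")
        take = idx[rng.choice(len(idx), min(n_per_class, len(idx)), replace=False)]
        ann[tuple(take.T)] = value
    return ann


def _segment_image(pre: Image2D, seg: SegmentationConfig, pixel_model):
    if seg.method == "pixelclassifier":
        return segment.classify_pixels(pre, pixel_model)
    return segment.threshold_segment(pre, seg.method, seg.fixed_level)


def _predict_objects(model, objects, names, image_id):
    rows = pd.DataFrame([o.descriptors for o in objects], columns=list(names))
    predicted, fractions = classify.predict_morphology(model, rows)
    for o, p in zip(objects, predicted):
        o.predicted_class = str(p)
    out = rows.copy()
    out.insert(0, "label", [o.label for o in objects])
    out.insert(0, "image_id", image_id)
    out["predicted_class"] = predicted
    for cls in model.classes:
        out[f"votes_{cls}"] = fractions[cls].to_numpy()
    return out


def run_pipeline_2d(cfg: PipelineConfig, out_dir) -> dict[str, Path]:
    """The 2D workflow: simulate, preprocess, segment, measure, classify,
    quantify.  Writes every intermediate under ``out_dir``."""
    cfg.validate()
    if cfg.mode != "2d":
        raise ValueError("run_pipeline_2d requires mode '2d'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seg = cfg.segmentation

    model, _ = _train_from_spec(cfg, _make_synth_spec(cfg, cfg.seed, False), out)

    pixel_model = None
    predictions, profiles = [], []
    for i in range(cfg.n_images):
        image_id = f"image_{i:03d}"
        t0 = time.perf_counter()
        spec = _make_synth_spec(cfg, cfg.seed + i, False)
        img_arr, truth = synthgen.render_image(spec)
        img = Image2D(img_arr, spec.pixel_size_um)
        write_image_tiff(out / f"{image_id}_raw.tif", img)
        write_image_tiff(out / f"{image_id}_truth.tif",
                         truth.label_map.astype(np.uint16), spec.pixel_size_um)
        write_table_csv(
            pd.DataFrame(
                {"label": list(truth.class_of_label),
                 "true_class": [c.value for c in truth.class_of_label.values()]}
            ),
            out / f"{image_id}_truth.csv",
        )
        pre = preprocess_pipeline(img, cfg.preprocess)
        write_image_tiff(out / f"{image_id}_preprocessed.tif", pre)
        if seg.method == "pixelclassifier" and pixel_model is None:
            ann = _sample_annotations(
                truth.label_map > 0,
                np.random.default_rng(cfg.seed + 90_000),
                seg.n_annotations_per_class,
            )
            pixel_model = segment.train_pixel_classifier(
                [pre], [ann], seed=cfg.seed + 90_001
            )
        mask = _segment_image(pre, seg, pixel_model)
        write_image_tiff(out / f"{image_id}_mask.tif",
                         mask.astype(np.uint8), spec.pixel_size_um)
        objects = segment.extract_objects_2d(mask, spec.pixel_size_um,
                                             seg.min_area_um2)
        for o in objects:
            descriptors.measure_2d(o)
        predictions.append(
            _predict_objects(model, objects, descriptors.DESCRIPTOR_NAMES_2D,
                             image_id)
        )
        profiles.append(quantify.percent_area_profile(objects, image_id))
        _log_stage("image_2d", t0, image_id=image_id, seed=spec.seed,
                   n_objects=len(objects), segmentation=seg.method)

    pred_df = pd.concat(predictions, ignore_index=True)
    write_table_csv(pred_df, out / "predictions.csv")
    write_table_csv(quantify.profiles_to_frame(profiles), out / "profiles.csv")
    return {
        "model": out / "model.joblib",
        "predictions": out / "predictions.csv",
        "profiles": out / "profiles.csv",
        "out_dir": out,
    }


def run_pipeline_3d(cfg: PipelineConfig, out_dir) -> dict[str, Path]:
    """The 3D workflow (confocal or EM): simulate a stack, segment slices,
    erode, label in 3D, measure, classify and quantify by volume."""
    cfg.validate()
    if cfg.mode not in ("3d-confocal", "3d-em"):
        raise ValueError("run_pipeline_3d requires a 3d mode")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seg = cfg.segmentation
    is_em = cfg.mode == "3d-em"

    # objects are measured at the post-compression voxel size in EM mode, so
    # the morphology classifier is trained at that same scale
    train_spec = _make_synth_spec(cfg, cfg.seed, True)
    if is_em:
        tvx, tvy, tvz = train_spec.voxel_size_um
        f = seg.em_downsample_factor
        train_spec = dataclasses.replace(
            train_spec, voxel_size_um=(tvx * f, tvy * f, tvz)
        )
    model, _ = _train_from_spec(cfg, train_spec, out)

    pixel_model = None
    predictions, profiles = [], []
    for i in range(cfg.n_images):
        image_id = f"stack_{i:03d}"
        t0 = time.perf_counter()
        spec = _make_synth_spec(cfg, cfg.seed + i, True)
        stack, truth = synthgen.render_volume(spec)
        write_image_tiff(out / f"{image_id}_raw.tif", stack)
        vx, vy, vz = spec.voxel_size_um
        truth_fg = truth.label_map > 0
        if is_em:
            # EM stacks are bright-background: invert, then compress in-plane
            stack = stack.max() - stack
            f = seg.em_downsample_factor
            stack = np.stack(
                [segment.downsample_em(Image2D(sl, vx), f).pixels for sl in stack]
            )
            # sample the truth support on the same downsampling grid
            rr = np.clip(np.round((np.arange(stack.shape[1]) + 0.5) * f - 0.5), 0,
                         truth_fg.shape[1] - 1).astype(int)
            cc = np.clip(np.round((np.arange(stack.shape[2]) + 0.5) * f - 0.5), 0,
                         truth_fg.shape[2] - 1).astype(int)
            truth_fg = truth_fg[:, rr][:, :, cc]
            vx, vy = vx * f, vy * f
        voxel = (vx, vy, vz)
        pre = np.stack(
            [preprocess_pipeline(Image2D(sl, vx), cfg.preprocess).pixels
             for sl in stack]
        )
        if seg.method == "pixelclassifier" and pixel_model is None:
            # train on the slice with the most object signal
            zi = int(np.argmax(truth_fg.sum(axis=(1, 2))))
            ann = _sample_annotations(
                truth_fg[zi], np.random.default_rng(cfg.seed + 90_000),
                seg.n_annotations_per_class,
            )
            pixel_model = segment.train_pixel_classifier(
                [Image2D(pre[zi], vx)], [ann], seed=cfg.seed + 90_001
            )
        t = np.stack(
            [_segment_image(Image2D(sl, vx), seg, pixel_model) for sl in pre]
        )
        eroded = np.stack([segment.erode_mask(sl, iterations=seg.erode_iterations)
                           for sl in t])
        write_image_tiff(out / f"{image_id}_mask.tif",
                         eroded.astype(np.uint8), vx)
        lmap, objects = segment.label_3d(eroded, seg.connectivity, voxel)
        objects = [o for o in objects if o.volume_um3 >= seg.min_volume_um3]
        for k, o in enumerate(objects, start=1):
            o.label = k
            descriptors.measure_3d(o)
        write_image_tiff(out / f"{image_id}_labels.tif",
                         lmap.labels.astype(np.uint16), vx)
        predictions.append(
            _predict_objects(model, objects, descriptors.DESCRIPTOR_NAMES_3D,
                             image_id)
        )
        profiles.append(quantify.percent_volume_profile(objects, image_id))
        _log_stage("stack_3d", t0, image_id=image_id, seed=spec.seed,
                   modality=spec.modality, n_objects=len(objects),
                   connectivity=seg.connectivity,
                   em_downsample=seg.em_downsample_factor if is_em else None)

    pred_df = pd.concat(predictions, ignore_index=True)
    write_table_csv(pred_df, out / "predictions.csv")
    write_table_csv(quantify.profiles_to_frame(profiles), out / "profiles.csv")
    return {
        "model": out / "model.joblib",
        "predictions": out / "predictions.csv",
        "profiles": out / "profiles.csv",
        "out_dir": out,
    }
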