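"""Dataset manifests, run configuration, checkpoints and provenance.

The metadata convention follows the public pediatric bone-age release:
a CSV with header ``id,boneage,male`` (male in {True, False}) next to a
directory of grayscale PNG/JPEG images named ``<id>.png`` / ``<id>.jpg``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .localization import ClusterNetConfig
from .preprocessing import PreprocessConfig
from .training import AgeStandardizer, AugmentConfig, TrainConfig

__all__ = [
    "ManifestError", "DatasetManifest", "read_manifest", "load_image",
    "RunConfig", "load_config", "save_config", "save_checkpoint",
    "load_checkpoint", "load_checkpoint_state", "write_provenance",
]

_IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


class ManifestError(ValueError):
    """Metadata table failed validation; message names the offending rows."""


@dataclass
class DatasetManifest:
    csv_path: Path
    image_dir: Path
    table: pd.DataFrame           # columns id (str), boneage (float), male (bool)

    def __len__(self):
        return len(self.table)

    def image_path(self, record_id: str) -> Path:
        for suffix in _IMAGE_SUFFIXES:
            p = self.image_dir / f"{record_id}{suffix}"
            if p.exists():
                return p
        raise FileNotFoundError(record_id)

    def load_images(self) -> dict[str, np.ndarray]:
        return {rid: load_image(self.image_path(rid)) for rid in self.table["id"]}


def load_image(path) -> np.ndarray:
    """Read a grayscale image as float in [0, 1]."""
    with Image.open(path) as img:
        return np.asarray(img.convert("L"), dtype=np.float64) / 255.0


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1"):
        return True
    if text in ("false", "0"):
        return False
    raise ValueError(f"not a boolean: {value!r}")


def read_manifest(csv_path, image_dir,
                  column_map: dict[str, str] | None = None) -> DatasetManifest:
    """Read and validate an ``id,boneage,male`` metadata CSV.

    ``column_map`` renames variant column headers onto the canonical schema,
    e.g. ``{"Image ID": "id"}``.  Every row must resolve to exactly one
    image file, parse a non-negative bone age and a boolean gender; failures
    are reported per row.
    """
    csv_path, image_dir = Path(csv_path), Path(image_dir)
    if not csv_path.exists():
        raise FileNotFoundError(csv_path)
    if not image_dir.is_dir():
        raise NotADirectoryError(image_dir)
    table = pd.read_csv(csv_path, dtype=str)
    if column_map:
        table = table.rename(columns=column_map)
    missing = {"id", "boneage", "male"} - set(table.columns)
    if missing:
        raise ManifestError(f"missing columns: {sorted(missing)}")

    errors, ids_seen = [], set()
    boneage, male = [], []
    for row in table.itertuples():
        rid = str(row.id)
        if rid in ids_seen:
            errors.append(f"row {row.Index}: duplicate id {rid!r}")
        ids_seen.add(rid)
        if not any((image_dir / f"{rid}{s}").exists() for s in _IMAGE_SUFFIXES):
            errors.append(f"row {row.Index}: no image file for id {rid!r}")
        try:
            age = float(row.boneage)
            if not np.isfinite(age) or age < 0:
                raise ValueError
            boneage.append(age)
        except (TypeError, ValueError):
            errors.append(f"row {row.Index}: unparsable bone age {row.boneage!r}")
            boneage.append(np.nan)
        try:
            male.append(_parse_bool(row.male))
        except ValueError:
            errors.append(f"row {row.Index}: non-boolean gender {row.male!r}")
            male.append(False)
    if errors:
        raise ManifestError("; ".join(errors))

    clean = pd.DataFrame({"id": table["id"].astype(str),
                          "boneage": boneage, "male": male})
    return DatasetManifest(csv_path=csv_path, image_dir=image_dir, table=clean)


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Nested configuration of every pipeline stage."""

    seed: int = 0
    clustering: ClusterNetConfig = field(default_factory=ClusterNetConfig)
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    training: TrainConfig = field(default_factory=TrainConfig)


def _from_mapping(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = fields[key].type
        if isinstance(value, dict):
            nested = {"ClusterNetConfig": ClusterNetConfig,
                      "PreprocessConfig": PreprocessConfig,
                      "TrainConfig": TrainConfig,
                      "AugmentConfig": AugmentConfig}.get(str(ftype).split(".")[-1].strip("'\" "))
            if nested is None and isinstance(ftype, type) and dataclasses.is_dataclass(ftype):
                nested = ftype
            if nested is not None:
                kwargs[key] = _from_mapping(nested, value)
                continue
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def _to_mapping(obj):
    out = {}
    for f in dataclasses.fields(obj):
        value = getattr(obj, f.name)
        if dataclasses.is_dataclass(value):
            out[f.name] = _to_mapping(value)
        elif isinstance(value, tuple):
            out[f.name] = list(value)
        else:
            out[f.name] = value
    return out


def load_config(path) -> RunConfig:
    """Read a YAML run config; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_mapping(RunConfig, data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_mapping(config), fh, sort_keys=False)


# --------------------------------------------------------------------------
# checkpoints and provenance
# --------------------------------------------------------------------------

def save_checkpoint(path, model, standardizer: AgeStandardizer,
                    config: TrainConfig) -> None:
    """Single-file checkpoint: parameter/buffer arrays plus a JSON header
    recording the input size, gender-embedding width and age standardizer."""
    from .architecture import GENDER_EMBED_DIM, MOBILENETV3_ROWS

    header = {
        "format": "handage-checkpoint-v1",
        "input_size": config.input_size,
        "use_gender": config.use_gender,
        "gender_embed_dim": GENDER_EMBED_DIM,
        "standardizer": {"mu": standardizer.mu, "sigma": standardizer.sigma},
        "train_config": _to_mapping(config),
        "architecture_rows": [_to_mapping(row) for row in MOBILENETV3_ROWS],
    }
    state = model.state_dict()
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
             **state)


def load_checkpoint_state(path) -> dict:
    with np.load(path) as data:
        return {k: data[k] for k in data.files if k != "__header__"}


def load_checkpoint(path):
    """Returns (model, standardizer, header)."""
    from .architecture import BoneAgeNet

    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        state = {k: data[k] for k in data.files if k != "__header__"}
    if header.get("format") != "handage-checkpoint-v1":
        raise ValueError("not a handage checkpoint")
    model = BoneAgeNet(use_gender=header["use_gender"])
    model.load_state_dict(state)
    model.eval()
    standardizer = AgeStandardizer(**header["standardizer"])
    return model, standardizer, header


def write_provenance(out_dir, config: RunConfig, stage: str) -> Path:
    """Record the config snapshot, seed and package version next to outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {"stage": stage, "seed": config.seed, "version": __version__,
              "config": _to_mapping(config)}
    path = out_dir / f"provenance_{stage}.json"
    path.write_text(json.dumps(record, indent=2))
    return path
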