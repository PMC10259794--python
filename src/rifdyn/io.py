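"""Readers/writers for the pipeline's artifact boundaries.

Movies travel as multi-page grayscale 16-bit TIFF with a YAML sidecar
carrying physical units (pixel size, frame interval, recording-start
offset); tables travel as schema-validated tidy CSV with fixed float
formatting so all writers are deterministic.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml


class FormatError(ValueError):
    pass


class SchemaError(ValueError):
    pass


DEFAULT_METADATA = {
    "pixel_size_nm": 100.0,
    "frame_interval_s": 60.0,
    "recording_start_offset_min": 4.0,
    "condition": "unknown",
    "nucleus_id": 0,
    "seed": 0,
}

_FLOAT_FORMAT = "%.10g"  # lossless round-trip to well below 1e-9 relative

OBSERVATION_SCHEMA: dict[str, str] = {
    "nucleus_id": "int", "frame": "int", "t_min": "float",
    "x_nm": "float", "y_nm": "float", "area_um2": "float",
    "intensity_au": "float",
}

TRACK_SCHEMA: dict[str, str] = {
    "track_id": "int", "nucleus_id": "int", "frame": "int", "t_min": "float",
    "x_com_nm": "float", "y_com_nm": "float", "area_um2": "float",
    "intensity_au": "float",
}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def write_movie(stack: np.ndarray, metadata: dict, path) -> Path:
    """Write a multi-page grayscale 16-bit TIFF plus YAML metadata sidecar."""
    path = Path(path)
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise FormatError(f"expected (frames, h, w) stack, got shape {stack.shape}")
    if stack.dtype != np.uint16:
        raise FormatError(f"expected uint16 pixel data, got {stack.dtype}")
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack, photometric="minisblack")
    meta = {**DEFAULT_METADATA, **metadata}
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return path


def read_movie(path) -> tuple[np.ndarray, dict]:
    """Read a movie TIFF and its sidecar; defaults (with warning) if absent."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        if tf.pages[0].samplesperpixel != 1:
            raise FormatError(f"{path.name}: RGB(A) TIFF is not supported; need grayscale")
        stack = tf.asarray()
    if stack.ndim == 2:
        stack = stack[None, ...]
    if stack.ndim != 3:
        raise FormatError(
            f"{path.name}: expected multi-page grayscale TIFF, got shape {stack.shape}")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = {**DEFAULT_METADATA, **(yaml.safe_load(fh) or {})}
    else:
        warnings.warn(
            f"{sidecar.name} not found; assuming defaults "
            f"(pixel {DEFAULT_METADATA['pixel_size_nm']} nm, "
            f"frame interval {DEFAULT_METADATA['frame_interval_s']} s)",
            RuntimeWarning, stacklevel=2)
        meta = dict(DEFAULT_METADATA)
    return stack, meta


def _validate_table(df: pd.DataFrame, schema: dict[str, str], what: str) -> pd.DataFrame:
    for col, kind in schema.items():
        if col not in df.columns:
            raise SchemaError(f"{what}: missing required column {col!r}")
        if kind == "int":
            if not pd.api.types.is_integer_dtype(df[col]):
                raise SchemaError(
                    f"{what}: column {col!r} must be integer, got {df[col].dtype}")
        elif not pd.api.types.is_numeric_dtype(df[col]):
            raise SchemaError(
                f"{what}: column {col!r} must be numeric, got {df[col].dtype}")
    extra = [c for c in df.columns if c not in schema]
    if extra:
        warnings.warn(f"{what}: extra columns preserved: {extra}",
                      RuntimeWarning, stacklevel=3)
    return df


def _write_table(df: pd.DataFrame, schema: dict[str, str], path, what: str) -> Path:
    _validate_table(df, schema, what)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ordered = [c for c in schema] + [c for c in df.columns if c not in schema]
    df[ordered].to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return path


def _read_table(path, schema: dict[str, str], what: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    return _validate_table(df, schema, what)


def write_observations_csv(df: pd.DataFrame, path) -> Path:
    return _write_table(df, OBSERVATION_SCHEMA, path, "observations")


def read_observations_csv(path) -> pd.DataFrame:
    return _read_table(path, OBSERVATION_SCHEMA, "observations")


def write_tracks_csv(df: pd.DataFrame, path) -> Path:
    return _write_table(df, TRACK_SCHEMA, path, "tracks")


def read_tracks_csv(path) -> pd.DataFrame:
    return _read_table(path, TRACK_SCHEMA, "tracks")


@dataclass
class RunConfig:
    """Validated top-level configuration of a pipeline run.

    The YAML layout mirrors this dataclass; unknown keys anywhere are
    rejected so silent typos cannot change an analysis.
    """

    conditions: tuple[str, ...] = ("gamma",)
    n_nuclei: int = 10
    n_frames: int = 300
    seed: int = 0
    outdir: str = "rifdyn_output"
    simulate: dict = field(default_factory=dict)  #: SimulationConfig overrides
    detect: dict = field(default_factory=dict)    #: DetectionParams overrides
    track: dict = field(default_factory=dict)     #: max_step_nm / max_gap overrides
    fit: dict = field(default_factory=dict)       #: MSD/fit overrides
    plots: bool = True

    def __post_init__(self) -> None:
        from .simulate import CONDITIONS
        self.conditions = tuple(self.conditions)
        for cond in self.conditions:
            if cond not in CONDITIONS:
                raise SchemaError(f"unknown condition {cond!r}")
        if self.n_nuclei < 1 or self.n_frames < 2:
            raise SchemaError("n_nuclei must be >= 1 and n_frames >= 2")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise SchemaError("run config must be a YAML mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
        return path
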