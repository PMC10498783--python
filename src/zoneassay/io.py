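"""Batch orchestration and file I/O.

Inventory of a time-lapse directory (one TIFF per well per timepoint),
frame loading, configuration, and the batch runner that applies one shared
segmentation parameter set to every frame.  A single parameter set per batch
is deliberate: per-well overrides would break comparability between wells.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .segment import PipelineParams, RGBFrame, run_pipeline

__all__ = [
    "SeriesEntry",
    "SeriesManifest",
    "load_frame",
    "discover_series",
    "run_batch",
    "load_config",
    "params_from_config",
    "load_layout",
]

logger = logging.getLogger("zoneassay")

DEFAULT_PATTERN = "{well}_t{index}.tif"


@dataclass(frozen=True)
class SeriesEntry:
    well_id: str
    time_index: int
    time_h: float
    path: Path


@dataclass(frozen=True)
class SeriesManifest:
    """Sorted inventory of (well, timepoint) -> file."""

    entries: tuple[SeriesEntry, ...]

    def __post_init__(self) -> None:
        keys = [(e.well_id, e.time_index) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (well_id, time_index) in manifest")

    def __len__(self) -> int:
        return len(self.entries)

    def wells(self) -> list[str]:
        return sorted({e.well_id for e in self.entries})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "well_id": e.well_id,
                    "time_index": e.time_index,
                    "time_h": e.time_h,
                    "path": str(e.path),
                }
                for e in self.entries
            ]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SeriesManifest":
        entries = tuple(
            SeriesEntry(
                str(r.well_id), int(r.time_index), float(r.time_h), Path(r.path)
            )
            for r in df.itertuples()
        )
        return cls(entries)


def load_frame(path: str | Path, pixel_scale_px_per_um: float) -> RGBFrame:
    """Read a TIFF as an 8-bit RGB frame with the given calibration.

    Grayscale TIFFs are promoted to three identical channels; any bit depth
    other than 8 per channel is rejected with an explicit error naming the
    file.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # unreadable / not a TIFF
        raise ValueError(f"cannot read TIFF {path}: {exc}") from exc
    if data.dtype != np.uint8:
        raise ValueError(
            f"unsupported bit depth in {path}: dtype {data.dtype}, expected uint8"
        )
    if data.ndim == 2:
        data = np.repeat(data[:, :, None], 3, axis=2)
    elif data.ndim == 3 and data.shape[2] == 3:
        pass
    else:
        raise ValueError(
            f"unsupported image layout in {path}: shape {data.shape}, "
            "expected (H, W) or (H, W, 3)"
        )
    return RGBFrame(data, pixel_scale_px_per_um)


def _pattern_to_regex(pattern: str) -> re.Pattern:
    """Turn a ``{well}_t{index}.tif``-style pattern into a regex."""
    if "{well}" not in pattern or "{index}" not in pattern:
        raise ValueError("filename pattern must contain {well} and {index}")
    escaped = re.escape(pattern)
    escaped = escaped.replace(re.escape("{well}"), r"(?P<well>.+?)")
    escaped = escaped.replace(re.escape("{index}"), r"(?P<index>\d+)")
    return re.compile("^" + escaped + "$")


def discover_series(
    directory: str | Path,
    filename_pattern: str = DEFAULT_PATTERN,
    frame_interval_h: float = 3.0,
) -> SeriesManifest:
    """Build a manifest from a directory of per-timepoint TIFFs.

    Filenames must match ``filename_pattern`` (named fields ``{well}`` and
    ``{index}``); non-matching files are ignored.  ``time_h`` is
    ``index * frame_interval_h``.  Gaps in a well's index sequence are
    reported as warnings, not errors; an empty match set raises.
    """
    directory = Path(directory)
    regex = _pattern_to_regex(filename_pattern)
    entries = []
    for path in sorted(directory.iterdir()) if directory.is_dir() else []:
        m = regex.match(path.name)
        if not m:
            continue
        idx = int(m.group("index"))
        entries.append(
            SeriesEntry(m.group("well"), idx, idx * frame_interval_h, path)
        )
    if not entries:
        raise ValueError(
            f"no files matching {filename_pattern!r} found in {directory}"
        )
    entries.sort(key=lambda e: (e.well_id, e.time_index))
    manifest = SeriesManifest(tuple(entries))
    for well in manifest.wells():
        idxs = [e.time_index for e in manifest.entries if e.well_id == well]
        missing = sorted(set(range(idxs[0], idxs[-1] + 1)) - set(idxs))
        if missing:
            logger.warning("well %s: missing timepoint indices %s", well, missing)
    return manifest


def run_batch(manifest: SeriesManifest, params: PipelineParams) -> tuple[pd.DataFrame, int]:
    """Run the segmentation chain on every manifest entry.

    One shared parameter set for the whole batch.  Per-frame failures are
    logged with (well, time) context and do not abort the run; the returned
    count of failures should be surfaced in the exit status.  Returns
    (long-format results table, n_failures).
    """
    rows = []
    n_failures = 0
    for e in manifest.entries:
        try:
            frame = load_frame(e.path, params.pixel_scale_px_per_um)
            result = run_pipeline(frame, params)
        except Exception as exc:
            n_failures += 1
            logger.error("well %s t=%gh (%s): %s", e.well_id, e.time_h, e.path, exc)
            continue
        for w in result.warnings:
            logger.warning("well %s t=%gh: %s", e.well_id, e.time_h, w)
        rows.append(
            {
                "well_id": e.well_id,
                "time_index": e.time_index,
                "time_h": e.time_h,
                "area_um2": result.area_um2,
                "area_mm2": result.area_mm2,
                "n_components": result.n_components_in_range,
                "warnings": "; ".join(result.warnings),
            }
        )
    return pd.DataFrame(rows), n_failures


_CONFIG_DEFAULTS = {
    "pixel_scale_px_per_um": 0.3525,
    "crop_fraction": 0.8,
    "erode_iterations": 1,
    "min_um2": 1e5,
    "max_um2": 7e8,
    "frame_interval_h": 3.0,
    "filename_pattern": DEFAULT_PATTERN,
    "correction": "sidak",
    "alpha": 0.05,
    "insert": {},
}


def load_config(path: str | Path | None = None) -> dict:
    """Load the YAML config, filling in documented defaults."""
    config = {k: v for k, v in _CONFIG_DEFAULTS.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config {path} must be a mapping")
        unknown = set(user) - set(_CONFIG_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config.update(user)
    return config


def params_from_config(config: dict, **overrides) -> PipelineParams:
    kwargs = {
        "pixel_scale_px_per_um": config["pixel_scale_px_per_um"],
        "crop_fraction": config["crop_fraction"],
        "erode_iterations": config["erode_iterations"],
        "min_um2": config["min_um2"],
        "max_um2": config["max_um2"],
    }
    kwargs.update(overrides)
    return PipelineParams(**kwargs)


def load_layout(path: str | Path) -> dict[str, str]:
    """Plate layout YAML: mapping well_id -> treatment.

    Accepts either a flat mapping or ``{wells: {A1: DMEM, ...}}``.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, dict) and "wells" in data:
        data = data["wells"]
    if not isinstance(data, dict) or not data:
        raise ValueError(f"layout {path} must map well ids to treatments")
    return {str(k): str(v) for k, v in data.items()}


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic CSV output: UTF-8, '.' decimal, repr-stable floats."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g", encoding="utf-8")
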