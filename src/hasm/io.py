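"""On-disk formats: landmark CSV tables, 16-bit multi-page TIFF heatmap
stacks with JSON sidecars, shape-model JSON, and the YAML run configuration.

Landmark CSV schema (one row per landmark, header required, UTF-8):
``image_id, landmark_index (1-22), x_px, y_px, pixel_spacing_mm (optional),
label (optional)``. Coordinates are serialized with 17 significant digits so
write-then-read roundtrips are lossless at double precision.

Heatmap stacks are stored as a 22-page 16-bit unsigned TIFF (page k =
landmark k, stored values = response x 65535 after per-channel
max-normalization) plus a JSON sidecar carrying the channel->image affine
metadata. Roundtrip quantization error is bounded by 1/65535 per pixel.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .heatmaps import HeatmapChannel, HeatmapStack
from .landmarks import N_LANDMARKS, LandmarkSet
from .model import HASMConfig


class FormatError(ValueError):
    """A file violated the documented schema."""


# ---------------------------------------------------------------------------
# Landmark CSV


def write_landmarks_csv(sets: Sequence[LandmarkSet], path: Union[str, Path]) -> None:
    rows = []
    for i, s in enumerate(sets):
        image_id = s.image_id if s.image_id is not None else f"image_{i:05d}"
        for j in range(N_LANDMARKS):
            rows.append(
                {
                    "image_id": image_id,
                    "landmark_index": j + 1,
                    "x_px": s.points[j, 0],
                    "y_px": s.points[j, 1],
                    "pixel_spacing_mm": s.pixel_spacing_mm,
                    "label": s.label,
                }
            )
    df = pd.DataFrame(rows, columns=[
        "image_id", "landmark_index", "x_px", "y_px", "pixel_spacing_mm", "label",
    ])
    df.to_csv(path, index=False, float_format="%.17g")


def read_landmarks_csv(path: Union[str, Path]) -> List[LandmarkSet]:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: missing header") from exc
    required = {"image_id", "landmark_index", "x_px", "y_px"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        return []
    for col in ("x_px", "y_px"):
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            row = bad.index[0] + 2  # 1-based with header
            raise FormatError(f"{path}: non-numeric {col} at row {row}")
        df[col] = pd.to_numeric(df[col])
    out: List[LandmarkSet] = []
    for image_id, group in df.groupby("image_id", sort=False):
        indices = group["landmark_index"].to_numpy()
        if len(np.unique(indices)) != len(indices):
            dupes = sorted({int(v) for v in indices[pd.Series(indices).duplicated()]})
            raise FormatError(f"{path}: image {image_id!r} duplicates landmark(s) {dupes}")
        present = set(int(v) for v in indices)
        expected = set(range(1, N_LANDMARKS + 1))
        if present != expected:
            miss = sorted(expected - present)
            raise FormatError(f"{path}: image {image_id!r} missing landmark(s) {miss}")
        g = group.set_index("landmark_index").sort_index()
        pts = g[["x_px", "y_px"]].to_numpy(dtype=float)
        spacing = None
        if "pixel_spacing_mm" in g.columns and not g["pixel_spacing_mm"].isna().all():
            spacing = float(g["pixel_spacing_mm"].iloc[0])
        label = None
        if "label" in g.columns and not g["label"].isna().all():
            label = str(g["label"].iloc[0])
        out.append(
            LandmarkSet(points=pts, pixel_spacing_mm=spacing, label=label, image_id=str(image_id))
        )
    return out


# ---------------------------------------------------------------------------
# Heatmap stack TIFF + sidecar


def write_heatmap_stack(
    stack: HeatmapStack, tiff_path: Union[str, Path], sidecar_path: Union[str, Path]
) -> None:
    shapes = {ch.response.shape for ch in stack.channels}
    if len(shapes) != 1:
        raise FormatError("all channels of a stack must share one grid size")
    pages = np.empty((N_LANDMARKS, *shapes.pop()), dtype=np.uint16)
    channels_meta = []
    for k, ch in enumerate(stack.channels):
        peak = ch.response.max()
        norm = ch.response / peak if peak > 0 else ch.response
        pages[k] = np.round(norm * 65535.0).astype(np.uint16)
        channels_meta.append(
            {
                "landmark_index": ch.landmark_index,
                "origin_offset": [ch.origin_offset[0], ch.origin_offset[1]],
                "scale": ch.scale,
                **({"sigma_hint": ch.sigma_hint} if ch.sigma_hint is not None else {}),
            }
        )
    tifffile.imwrite(tiff_path, pages)
    sidecar = {
        "image_id": stack.image_id,
        "pixel_spacing_mm": stack.pixel_spacing_mm,
        "channels": channels_meta,
    }
    Path(sidecar_path).write_text(json.dumps(sidecar))


def read_heatmap_stack(
    tiff_path: Union[str, Path], sidecar_path: Union[str, Path]
) -> HeatmapStack:
    try:
        pages = tifffile.imread(tiff_path)
    except Exception as exc:
        raise FormatError(f"{tiff_path}: unreadable TIFF ({exc})") from exc
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] != N_LANDMARKS:
        raise FormatError(
            f"{tiff_path}: expected {N_LANDMARKS} pages, found {pages.shape[0]}"
        )
    meta = json.loads(Path(sidecar_path).read_text())
    channels_meta = meta.get("channels", [])
    if len(channels_meta) != N_LANDMARKS:
        raise FormatError(f"{sidecar_path}: expected {N_LANDMARKS} channel entries")
    # sidecar entries are keyed by landmark_index; page order is index order
    by_index = {}
    for entry in channels_meta:
        idx = int(entry["landmark_index"])
        if idx in by_index:
            raise FormatError(f"{sidecar_path}: duplicate landmark_index {idx}")
        by_index[idx] = entry
    if set(by_index) != set(range(1, N_LANDMARKS + 1)):
        raise FormatError(f"{sidecar_path}: channel indices must cover 1..22")
    channels = []
    for k in range(1, N_LANDMARKS + 1):
        entry = by_index[k]
        channels.append(
            HeatmapChannel(
                response=pages[k - 1].astype(float) / 65535.0,
                origin_offset=tuple(entry["origin_offset"]),
                scale=float(entry["scale"]),
                landmark_index=k,
                sigma_hint=entry.get("sigma_hint"),
            )
        )
    return HeatmapStack(
        channels=channels,
        image_id=meta.get("image_id"),
        pixel_spacing_mm=meta.get("pixel_spacing_mm"),
    )


# ---------------------------------------------------------------------------
# Run configuration


@dataclasses.dataclass
class RunConfig:
    """YAML-backed run configuration; unknown keys are rejected."""

    hasm: HASMConfig = dataclasses.field(default_factory=HASMConfig)
    model_path: Optional[str] = None
    heatmap_tiff: Optional[str] = None
    heatmap_sidecar: Optional[str] = None
    landmarks_csv: Optional[str] = None
    output: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise FormatError(f"{path}: top level must be a mapping")
        hasm_keys = {f.name for f in dataclasses.fields(HASMConfig)}
        own_keys = {f.name for f in dataclasses.fields(cls)} - {"hasm"}
        hasm_kwargs, own_kwargs = {}, {}
        for key, value in raw.items():
            if key in hasm_keys:
                hasm_kwargs[key] = value
            elif key in own_keys:
                own_kwargs[key] = value
            else:
                raise FormatError(f"{path}: unknown configuration key {key!r}")
        try:
            return cls(hasm=HASMConfig(**hasm_kwargs), **own_kwargs)
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
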