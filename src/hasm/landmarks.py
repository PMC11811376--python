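"""Landmark containers and shape-vector layout.

A lumbar landmark configuration consists of 22 points in the image frame
(x = columns increasing rightward, y = rows increasing downward, 0-based,
pixel centers at integer coordinates):

* vertebrae L1..L5 (vertebra index 1..5): landmarks ``4*(j-1)+1 .. 4*j`` in
  the order upper-left (UL), upper-right (UR), lower-left (LL),
  lower-right (LR);
* sacrum S1 (vertebra index 6): landmarks 21 and 22, the left and right
  endpoints of the upper endplate.

The flat shape-vector layout is ``(x_1, ..., x_22, y_1, ..., y_22)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

N_LANDMARKS = 22
N_VERTEBRAE = 6  # L1..L5 plus the S1 upper endplate
SHAPE_DIM = 2 * N_LANDMARKS

LABEL_NORMAL = "normal"
LABEL_SPONDYLOLISTHESIS = "spondylolisthesis"
_VALID_LABELS = (LABEL_NORMAL, LABEL_SPONDYLOLISTHESIS)


class LandmarkError(ValueError):
    """Structural problem with a landmark configuration."""


def vertebra_landmark_indices(vertebra: int) -> np.ndarray:
    """0-based landmark indices belonging to vertebra ``vertebra`` (1..6)."""
    if not 1 <= vertebra <= N_VERTEBRAE:
        raise LandmarkError(f"vertebra index must be in 1..6, got {vertebra}")
    if vertebra == 6:
        return np.array([20, 21])
    start = 4 * (vertebra - 1)
    return np.arange(start, start + 4)


@dataclass(frozen=True)
class LandmarkSet:
    """Ordered set of the 22 lumbar landmarks of one image.

    Parameters
    ----------
    points
        ``(22, 2)`` float array of ``(x, y)`` image-frame coordinates.
    pixel_spacing_mm
        Optional millimetres per pixel (isotropic).
    label
        Optional ``"normal"`` or ``"spondylolisthesis"``.
    image_id
        Optional identifier used by the CSV readers/writers.
    """

    points: np.ndarray
    pixel_spacing_mm: Optional[float] = None
    label: Optional[str] = None
    image_id: Optional[str] = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise LandmarkError(
                f"expected {N_LANDMARKS} (x, y) points, got array of shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise LandmarkError("landmark coordinates must be finite")
        if self.pixel_spacing_mm is not None and not self.pixel_spacing_mm > 0:
            raise LandmarkError("pixel_spacing_mm must be positive")
        if self.label is not None and self.label not in _VALID_LABELS:
            raise LandmarkError(f"label must be one of {_VALID_LABELS}")
        object.__setattr__(self, "points", pts)

    def with_points(self, points: np.ndarray) -> "LandmarkSet":
        return replace(self, points=np.asarray(points, dtype=float))

    def with_label(self, label: str) -> "LandmarkSet":
        return replace(self, label=label)

    def vertebra_points(self, vertebra: int) -> np.ndarray:
        return self.points[vertebra_landmark_indices(vertebra)]


def to_shape_vector(landmarks: LandmarkSet) -> np.ndarray:
    """Flatten a LandmarkSet to the 44-vector ``(x_1..x_22, y_1..y_22)``."""
    return np.concatenate([landmarks.points[:, 0], landmarks.points[:, 1]])


def from_shape_vector(vector: np.ndarray, template: Optional[LandmarkSet] = None) -> LandmarkSet:
    """Inverse of :func:`to_shape_vector`.

    ``template``, if given, supplies the metadata (spacing, label, image_id).
    """
    v = np.asarray(vector, dtype=float)
    if v.shape != (SHAPE_DIM,):
        raise LandmarkError(f"shape vector must have length {SHAPE_DIM}, got shape {v.shape}")
    pts = np.column_stack([v[:N_LANDMARKS], v[N_LANDMARKS:]])
    if template is None:
        return LandmarkSet(points=pts)
    return template.with_points(pts)


def vector_to_points(vector: np.ndarray) -> np.ndarray:
    """View a 44-vector as a ``(22, 2)`` point array (no metadata)."""
    v = np.asarray(vector, dtype=float)
    if v.shape[-1] != SHAPE_DIM:
        raise LandmarkError(f"expected last dimension {SHAPE_DIM}, got {v.shape}")
    return np.stack([v[..., :N_LANDMARKS], v[..., N_LANDMARKS:]], axis=-1)


def points_to_vector(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.shape[-2:] != (N_LANDMARKS, 2):
        raise LandmarkError(f"expected trailing shape ({N_LANDMARKS}, 2), got {pts.shape}")
    return np.concatenate([pts[..., 0], pts[..., 1]], axis=-1)
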