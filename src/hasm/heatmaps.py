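"""Per-landmark heatmap channels, Gaussian rendering, Sobel gradient fields,
subpixel gradient sampling, and initial argmax detection.

Each landmark has its own response grid (a CNN-output surrogate over a
sub-image) with an affine channel->image mapping
``image = origin_offset + channel_pos / scale`` where ``scale`` is
channel-pixels per image-pixel. Coordinates are 0-based ``(x, y)`` with
pixel centers at integer positions, x along columns, y along rows downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .landmarks import N_LANDMARKS, LandmarkSet


class HeatmapError(ValueError):
    """Structural problem with a heatmap channel or stack."""


class OutOfBoundsError(ValueError):
    """A sample position fell outside the channel grid."""


@dataclass
class HeatmapChannel:
    """One landmark's nonnegative response grid plus its image-frame mapping."""

    response: np.ndarray
    origin_offset: Tuple[float, float]
    scale: float
    landmark_index: int
    sigma_hint: Optional[float] = None

    def __post_init__(self) -> None:
        r = np.asarray(self.response, dtype=float)
        if r.ndim != 2 or r.shape[0] < 3 or r.shape[1] < 3:
            raise HeatmapError("response must be a 2D grid of at least 3x3")
        if not np.all(np.isfinite(r)) or np.any(r < 0):
            raise HeatmapError("responses must be finite and nonnegative")
        if not self.scale > 0:
            raise HeatmapError("scale must be positive")
        if not 1 <= self.landmark_index <= N_LANDMARKS:
            raise HeatmapError("landmark_index must be in 1..22")
        self.response = r
        self.origin_offset = (float(self.origin_offset[0]), float(self.origin_offset[1]))

    @property
    def shape(self) -> Tuple[int, int]:
        return self.response.shape  # (H, W)

    def channel_to_image(self, pos: np.ndarray) -> np.ndarray:
        """Affine map ``image = offset + channel_pos / scale`` on (x, y)."""
        pos = np.asarray(pos, dtype=float)
        return np.asarray(self.origin_offset) + pos / self.scale

    def image_to_channel(self, pos: np.ndarray) -> np.ndarray:
        pos = np.asarray(pos, dtype=float)
        return (pos - np.asarray(self.origin_offset)) * self.scale

    def contains(self, channel_pos: np.ndarray) -> bool:
        """True when the (x, y) channel position lies inside the grid."""
        x, y = float(channel_pos[0]), float(channel_pos[1])
        h, w = self.response.shape
        return 0.0 <= x <= w - 1 and 0.0 <= y <= h - 1

    def argmax_channel(self) -> np.ndarray:
        """Grid argmax in channel (x, y); ties broken by smallest row-major index."""
        flat = int(np.argmax(self.response))
        row, col = np.unravel_index(flat, self.response.shape)
        return np.array([float(col), float(row)])

    def argmax_image(self) -> np.ndarray:
        return self.channel_to_image(self.argmax_channel())


@dataclass
class HeatmapStack:
    """The 22 per-landmark channels of one image, slot k = landmark k."""

    channels: List[HeatmapChannel]
    image_id: Optional[str] = None
    pixel_spacing_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.channels) != N_LANDMARKS:
            raise HeatmapError(f"expected {N_LANDMARKS} channels, got {len(self.channels)}")
        indices = sorted(c.landmark_index for c in self.channels)
        if indices != list(range(1, N_LANDMARKS + 1)):
            raise HeatmapError("need exactly one channel per landmark index 1..22")
        self.channels = sorted(self.channels, key=lambda c: c.landmark_index)

    def channel(self, landmark_index: int) -> HeatmapChannel:
        return self.channels[landmark_index - 1]


@dataclass
class GradientField:
    """Sobel gradient magnitude ``M`` and orientation ``O`` of one channel.

    ``O`` is measured in the channel array frame (x = columns rightward,
    y = rows downward) and points toward increasing response.
    """

    M: np.ndarray
    O: np.ndarray


def render_gaussian(
    center: Sequence[float], sigma: float, shape: Tuple[int, int]
) -> np.ndarray:
    """Unit-amplitude isotropic Gaussian ``exp(-r^2 / (2 sigma^2))`` on an
    ``(H, W)`` grid; ``center`` is in channel (x, y) coordinates."""
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    h, w = shape
    cx, cy = float(center[0]), float(center[1])
    x = np.arange(w)[None, :]
    y = np.arange(h)[:, None]
    return np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * sigma**2))


def compute_gradient_field(channel: HeatmapChannel, normalize: bool = True) -> GradientField:
    """Sobel gradients of the response, 1/8-scaled with replicate borders.

    The 1/8 scaling makes the Sobel output equal the true derivative on
    affine surfaces, so the gradient step size is comparable across
    resolutions. With ``normalize`` the response is first divided by its
    maximum (a no-op on an all-zero channel).
    """
    resp = channel.response
    if normalize:
        peak = resp.max()
        if peak > 0:
            resp = resp / peak
    gx = ndimage.sobel(resp, axis=1, mode="nearest") / 8.0
    gy = ndimage.sobel(resp, axis=0, mode="nearest") / 8.0
    return GradientField(M=np.hypot(gx, gy), O=np.arctan2(gy, gx))


def sample_gradient(fieldv: GradientField, pos: Sequence[float]) -> Tuple[float, float]:
    """Bilinear gradient sample at a subpixel channel position.

    The Cartesian components ``(M cos O, M sin O)`` are interpolated (never
    the angles, which wrap at +-pi); returns ``(m_h, o_h)`` of the
    interpolated vector.
    """
    x, y = float(pos[0]), float(pos[1])
    h, w = fieldv.M.shape
    if not (0.0 <= x <= w - 1 and 0.0 <= y <= h - 1):
        raise OutOfBoundsError(f"position ({x}, {y}) outside channel grid {w}x{h}")
    cx = fieldv.M * np.cos(fieldv.O)
    cy = fieldv.M * np.sin(fieldv.O)
    coords = np.array([[y], [x]])
    vx = float(ndimage.map_coordinates(cx, coords, order=1, mode="nearest")[0])
    vy = float(ndimage.map_coordinates(cy, coords, order=1, mode="nearest")[0])
    return float(np.hypot(vx, vy)), float(np.arctan2(vy, vx))


def detect_initial(
    stack: HeatmapStack, with_flags: bool = False
):
    """Initial landmarks: per-channel grid argmax mapped to the image frame.

    An all-zero channel yields the channel center with an "undetected" flag.
    With ``with_flags`` returns ``(LandmarkSet, flags)``.
    """
    pts = np.empty((N_LANDMARKS, 2))
    flags = np.zeros(N_LANDMARKS, dtype=bool)
    for k, ch in enumerate(stack.channels):
        if ch.response.max() <= 0:
            h, w = ch.response.shape
            pts[k] = ch.channel_to_image([(w - 1) / 2.0, (h - 1) / 2.0])
            flags[k] = True
        else:
            pts[k] = ch.argmax_image()
    result = LandmarkSet(
        points=pts, image_id=stack.image_id, pixel_spacing_mm=stack.pixel_spacing_mm
    )
    if with_flags:
        return result, flags
    return result
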