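"""Synthetic lumbar-spine landmark configurations and corrupted heatmap stacks.

Stands in for a radiograph dataset plus a trained CNN so every stage of the
correction pipeline is exercisable offline. The generator is
parametric-geometric: five convex vertebral quadrilaterals (L1..L5) and the
S1 upper-endplate segment are stacked top to bottom along a smoothly curved
centerline with sampled sizes, gaps, and tilts, plus per-landmark labeling
jitter emulating inter-rater ground-truth variability. Spondylolisthesis
cases are produced by the slip augmentation. Heatmap channels are clean
Gaussians over per-landmark sub-windows, optionally corrupted the way CNN
outputs fail: shifted peaks, spurious secondary peaks, attenuated peaks, and
additive pixel noise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .augmentation import (
    AugmentationParams,
    augment_spondylolisthesis,
    sample_augmentation_params,
)
from .heatmaps import HeatmapChannel, HeatmapStack, render_gaussian
from .landmarks import LABEL_NORMAL, N_LANDMARKS, LandmarkSet


@dataclass(frozen=True)
class SpineTemplateParams:
    """Geometry of the generated spine population (pixels, radians)."""

    n_images: int = 100
    vertebra_width_px: float = 48.0
    width_cv: float = 0.04
    vertebra_height_px: float = 30.0
    height_cv: float = 0.04
    aspect_cv: float = 0.10
    gap_px: float = 10.0
    gap_cv: float = 0.08
    disc_cv: float = 0.20
    curvature_amplitude_px: float = 12.0
    tilt_spread_rad: float = 0.04
    landmark_jitter_px: float = 0.5
    spondylolisthesis_fraction: float = 0.15
    slip_beta_range: Tuple[float, float] = (0.05, 0.3)
    extent: Tuple[int, int] = (320, 256)  # (H, W)
    pixel_spacing_mm: float = 0.17

    def __post_init__(self) -> None:
        for name in ("width_cv", "height_cv", "gap_cv", "tilt_spread_rad", "landmark_jitter_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.spondylolisthesis_fraction <= 1:
            raise ValueError("spondylolisthesis_fraction must be in [0, 1]")


@dataclass(frozen=True)
class HeatmapNoiseParams:
    """Corruption model for simulated heatmap channels."""

    sigma: float = 5.0
    peak_shift_prob: float = 0.0
    peak_shift_range: Tuple[float, float] = (10.0, 30.0)
    spurious_prob: float = 0.0
    spurious_amplitude_range: Tuple[float, float] = (0.3, 0.9)
    attenuation_prob: float = 0.0
    attenuation_floor: float = 0.3
    noise_std: float = 0.0
    channel_size: int = 128
    channel_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("peak_shift_prob", "spurious_prob", "attenuation_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not 0 <= self.attenuation_floor <= 1:
            raise ValueError("attenuation_floor must be in [0, 1]")


def generate_spine(rng: np.random.Generator, params: SpineTemplateParams) -> LandmarkSet:
    """One normal 22-landmark configuration.

    Vertebra centers descend strictly in y; each quadrilateral is a tilted
    rectangle (convex by construction, jitter permitting).
    """
    p = params
    # per-subject shared factors: vertebral aspect (body height relative to
    # width) and disc height are strongly correlated along the spine, unlike
    # the smaller independent per-vertebra residuals
    aspect = 1 + p.aspect_cv * rng.standard_normal()
    disc = 1 + p.disc_cv * rng.standard_normal()
    widths = p.vertebra_width_px * (1 + p.width_cv * rng.standard_normal(6))
    heights = p.vertebra_height_px * np.clip(aspect, 0.5, None) * (
        1 + p.height_cv * rng.standard_normal(5)
    )
    gaps = p.gap_px * np.clip(disc, 0.3, None) * (1 + p.gap_cv * rng.standard_normal(5))
    widths = np.clip(widths, 0.3 * p.vertebra_width_px, None)
    heights = np.clip(heights, 0.3 * p.vertebra_height_px, None)
    gaps = np.clip(gaps, 0.2 * p.gap_px, None)
    # S1 endplate slightly wider than the lumbar bodies, as on lateral films
    widths[5] *= 1.1

    h_img, w_img = p.extent
    total = heights.sum() + gaps.sum()
    y = (h_img - total) / 2.0
    if y < 0:
        raise ValueError("template does not fit in the requested extent")
    phase = rng.uniform(0, 2 * np.pi)
    x_mid = w_img / 2.0

    def centerline_x(yy: float) -> float:
        return x_mid + p.curvature_amplitude_px * np.sin(np.pi * yy / h_img + phase)

    def centerline_tilt(yy: float) -> float:
        # slope of x(y) converted to a rotation of the vertebral axes
        dxdy = (
            p.curvature_amplitude_px * np.pi / h_img * np.cos(np.pi * yy / h_img + phase)
        )
        return float(np.arctan(dxdy))

    pts = np.empty((N_LANDMARKS, 2))
    for j in range(5):
        cy = y + heights[j] / 2.0
        cx = centerline_x(cy)
        tilt = centerline_tilt(cy) + p.tilt_spread_rad * rng.standard_normal()
        c, s = np.cos(tilt), np.sin(tilt)
        rot = np.array([[c, -s], [s, c]])
        half_w, half_h = widths[j] / 2.0, heights[j] / 2.0
        corners = np.array(
            [[-half_w, -half_h], [half_w, -half_h], [-half_w, half_h], [half_w, half_h]]
        )
        pts[4 * j : 4 * j + 4] = corners @ rot.T + np.array([cx, cy])
        y += heights[j] + gaps[j]
    # S1 upper endplate
    cx = centerline_x(y)
    tilt = centerline_tilt(y) + p.tilt_spread_rad * rng.standard_normal()
    c, s = np.cos(tilt), np.sin(tilt)
    rot = np.array([[c, -s], [s, c]])
    half_w = widths[5] / 2.0
    ends = np.array([[-half_w, 0.0], [half_w, 0.0]])
    pts[20:22] = ends @ rot.T + np.array([cx, y])

    pts += p.landmark_jitter_px * rng.standard_normal(pts.shape)
    if np.any(pts < 0) or np.any(pts[:, 0] > w_img - 1) or np.any(pts[:, 1] > h_img - 1):
        raise ValueError("generated landmarks fall outside the image extent")
    return LandmarkSet(points=pts, pixel_spacing_mm=p.pixel_spacing_mm, label=LABEL_NORMAL)


def generate_dataset(
    rng: np.random.Generator, params: SpineTemplateParams
) -> List[LandmarkSet]:
    """Draw ``n_images`` configurations; a ``spondylolisthesis_fraction`` of
    them (in expectation) receive a sampled slip and are labelled so."""
    out: List[LandmarkSet] = []
    lo, hi = params.slip_beta_range
    for i in range(params.n_images):
        spine = generate_spine(rng, params)
        if rng.uniform() < params.spondylolisthesis_fraction:
            aug = sample_augmentation_params(rng)
            beta = float(rng.uniform(lo, hi))
            aug = AugmentationParams(
                v_start=aug.v_start, v_end=aug.v_end, alpha=aug.alpha,
                beta=beta, beta_max=max(aug.beta_max, hi),
            )
            spine = augment_spondylolisthesis(spine, aug)
        out.append(
            LandmarkSet(
                points=spine.points,
                pixel_spacing_mm=spine.pixel_spacing_mm,
                label=spine.label,
                image_id=f"synthetic_{i:05d}",
            )
        )
    return out


def simulate_heatmaps(
    truth: LandmarkSet,
    noise: HeatmapNoiseParams,
    rng: np.random.Generator,
    peak_overrides: Optional[Dict[int, np.ndarray]] = None,
) -> HeatmapStack:
    """Render the 22-channel heatmap stack of one configuration.

    Each channel is a sub-window centred on the true landmark; the Gaussian
    peak sits at the true position unless corrupted (or overridden via
    ``peak_overrides``, a map of landmark index to image-frame peak
    position — used to construct controlled benchmarks).
    """
    n = noise.channel_size
    scale = noise.channel_scale
    half = (n - 1) / 2.0
    channels = []
    for k in range(N_LANDMARKS):
        true_pos = truth.points[k]
        offset = true_pos - np.array([half, half]) / scale
        peak_img = np.array(true_pos, dtype=float)
        if peak_overrides is not None and (k + 1) in peak_overrides:
            peak_img = np.asarray(peak_overrides[k + 1], dtype=float)
        elif noise.peak_shift_prob > 0 and rng.uniform() < noise.peak_shift_prob:
            angle = rng.uniform(0, 2 * np.pi)
            dist = rng.uniform(*noise.peak_shift_range)
            peak_img = true_pos + dist * np.array([np.cos(angle), np.sin(angle)])
        peak_ch = (peak_img - offset) * scale
        resp = render_gaussian(peak_ch, noise.sigma * scale, (n, n))
        if noise.attenuation_prob > 0 and rng.uniform() < noise.attenuation_prob:
            resp = resp * rng.uniform(noise.attenuation_floor, 1.0)
        if noise.spurious_prob > 0 and rng.uniform() < noise.spurious_prob:
            amp = rng.uniform(*noise.spurious_amplitude_range)
            spur = np.array([rng.uniform(0, n - 1), rng.uniform(0, n - 1)])
            resp = resp + amp * render_gaussian(spur, noise.sigma * scale, (n, n))
        if noise.noise_std > 0:
            resp = resp + noise.noise_std * rng.standard_normal(resp.shape)
        resp = np.clip(resp, 0.0, None)
        channels.append(
            HeatmapChannel(
                response=resp,
                origin_offset=(float(offset[0]), float(offset[1])),
                scale=scale,
                landmark_index=k + 1,
                sigma_hint=noise.sigma,
            )
        )
    return HeatmapStack(
        channels=channels,
        image_id=truth.image_id,
        pixel_spacing_mm=truth.pixel_spacing_mm,
    )


def make_fixture(
    seed: int,
    out_dir,
    n_train: int = 30,
    n_validation: int = 3,
    template: Optional[SpineTemplateParams] = None,
    noise: Optional[HeatmapNoiseParams] = None,
) -> dict:
    """Write a complete miniature experiment to ``out_dir``.

    Produces a training landmark CSV, a fitted shape-model JSON, clean
    validation heatmap stacks with their ground-truth CSV, and a manifest of
    seeds, parameters, and content hashes. Byte-reproducible per seed.
    """
    from .io import write_heatmap_stack, write_landmarks_csv
    from .shapes import ShapeModel

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    template = template or SpineTemplateParams(n_images=n_train)
    noise = noise or HeatmapNoiseParams()
    rng = np.random.default_rng(seed)
    train = generate_dataset(rng, template)
    model = ShapeModel.fit(train, metadata={"seed": seed})

    val_params = SpineTemplateParams(
        **{**asdict(template), "n_images": n_validation, "spondylolisthesis_fraction": 0.0}
    )
    validation = generate_dataset(np.random.default_rng(seed + 1), val_params)

    train_csv = out / "train_landmarks.csv"
    truth_csv = out / "validation_truth.csv"
    model_json = out / "shape_model.json"
    write_landmarks_csv(train, train_csv)
    write_landmarks_csv(validation, truth_csv)
    model.to_json(model_json)
    stack_files = []
    stack_rng = np.random.default_rng(seed + 2)
    for i, truth in enumerate(validation):
        stack = simulate_heatmaps(truth, noise, stack_rng)
        tiff = out / f"stack_{i:03d}.tiff"
        sidecar = out / f"stack_{i:03d}.json"
        write_heatmap_stack(stack, tiff, sidecar)
        stack_files += [tiff.name, sidecar.name]

    def _sha(path: Path) -> str:
        return hashlib.sha256(path.read_bytes()).hexdigest()

    files = [train_csv.name, truth_csv.name, model_json.name] + stack_files
    manifest = {
        "seed": seed,
        "template": asdict(template),
        "noise": asdict(noise),
        "files": {name: _sha(out / name) for name in sorted(files)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
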