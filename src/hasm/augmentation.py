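"""Artificial spondylolisthesis augmentation of landmark configurations.

Spondylolisthesis is an anterior/posterior slip of a vertebra relative to the
one below. A biased shape model trained mostly on normal spines would
"correct" slipped configurations back toward normality, so the training set
is de-biased by rigidly translating a consecutive block of vertebrae in
otherwise-normal configurations.

The slip is parametrized by four values: ``v_start`` and ``v_end`` select the
consecutive vertebrae to move (1..5 = L1..L5, 6 = the S1 upper endplate),
``alpha`` in {-1, +1} sets forward/backward direction, and ``beta`` in
``[0, beta_max]`` scales the displacement by the length of the top edge
(UL -> UR) of the first moved vertebra. ``beta_max`` defaults to 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .landmarks import (
    LABEL_NORMAL,
    LABEL_SPONDYLOLISTHESIS,
    N_VERTEBRAE,
    LandmarkSet,
    vertebra_landmark_indices,
)

BETA_MAX_DEFAULT = 0.3


@dataclass(frozen=True)
class AugmentationParams:
    """Slip parameters ``(v_start, v_end, alpha, beta)``."""

    v_start: int
    v_end: int
    alpha: int
    beta: float
    beta_max: float = BETA_MAX_DEFAULT

    def __post_init__(self) -> None:
        if not (1 <= self.v_start <= N_VERTEBRAE and 1 <= self.v_end <= N_VERTEBRAE):
            raise ValueError("v_start and v_end must be in 1..6")
        if self.v_start > self.v_end:
            raise ValueError("v_start must not exceed v_end")
        if self.alpha not in (-1, 1):
            raise ValueError("alpha must be -1 or +1")
        if not 0 <= self.beta <= self.beta_max:
            raise ValueError(f"beta must lie in [0, {self.beta_max}]")


def augment_spondylolisthesis(
    landmarks: LandmarkSet, params: AugmentationParams
) -> LandmarkSet:
    """Rigidly translate vertebrae ``v_start..v_end`` along the slip axis.

    The displacement is ``alpha * beta * (UR* - UL*)`` where ``UL*``/``UR*``
    are the top two points of the first moved vertebra (for the sacrum these
    are its two endplate endpoints). All other landmarks are untouched
    bit-exact; the output is labelled spondylolisthesis.
    """
    top = landmarks.vertebra_points(params.v_start)
    ul, ur = top[0], top[1]
    d = params.alpha * params.beta * (ur - ul)
    moved = np.concatenate(
        [vertebra_landmark_indices(v) for v in range(params.v_start, params.v_end + 1)]
    )
    pts = landmarks.points.copy()
    pts[moved] += d
    return landmarks.with_points(pts).with_label(LABEL_SPONDYLOLISTHESIS)


def sample_augmentation_params(
    rng: np.random.Generator,
    beta_max: float = BETA_MAX_DEFAULT,
    fix_v_end: Optional[int] = None,
) -> AugmentationParams:
    """Draw slip parameters: ``v_start`` uniform on 1..6, ``v_end`` uniform on
    ``v_start..6`` (or fixed via ``fix_v_end``), ``alpha`` uniform on
    {-1, +1}, ``beta`` uniform on ``[0, beta_max]``."""
    if fix_v_end is not None:
        v_start = int(rng.integers(1, fix_v_end + 1))
        v_end = fix_v_end
    else:
        v_start = int(rng.integers(1, N_VERTEBRAE + 1))
        v_end = int(rng.integers(v_start, N_VERTEBRAE + 1))
    alpha = int(rng.choice([-1, 1]))
    beta = float(rng.uniform(0.0, beta_max))
    return AugmentationParams(v_start=v_start, v_end=v_end, alpha=alpha, beta=beta, beta_max=beta_max)


def balance_training_set(
    shapes: Sequence[LandmarkSet],
    rng: np.random.Generator,
    target_fraction: float = 0.15,
    beta_max: float = BETA_MAX_DEFAULT,
) -> Tuple[List[LandmarkSet], List[AugmentationParams]]:
    """Append augmented spondylolisthesis copies until their fraction reaches
    ``target_fraction``.

    Labels are taken from each LandmarkSet (missing label counts as normal).
    Originals are returned untouched, followed by the appended augmented
    copies of randomly chosen normal shapes. Also returns the sampled slip
    parameters, one per appended shape.
    """
    if not 0 < target_fraction < 1:
        raise ValueError("target_fraction must be in (0, 1)")
    shapes = list(shapes)
    normals = [s for s in shapes if s.label != LABEL_SPONDYLOLISTHESIS]
    n_spondy = len(shapes) - len(normals)
    n_total = len(shapes)
    out = list(shapes)
    params_used: List[AugmentationParams] = []
    if n_total and n_spondy / n_total >= target_fraction:
        return out, params_used
    if not normals:
        raise ValueError("no normal shapes available to augment")
    while (n_spondy + len(params_used)) / (n_total + len(params_used)) < target_fraction:
        src = normals[int(rng.integers(len(normals)))]
        params = sample_augmentation_params(rng, beta_max=beta_max)
        params_used.append(params)
        out.append(augment_spondylolisthesis(src, params))
    return out, params_used
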