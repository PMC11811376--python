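"""Evaluation indices for landmark detection on lumbar spine images.

Per image ``i`` and landmark ``j`` the point error ``E_ij`` is the Euclidean
distance between detection and ground truth. The per-image summaries
``E_max,i`` / ``E_mean,i`` average over landmarks; their dataset means are
``AE_max`` / ``AE_mean``. The allowable error ``E_a,i`` — 20% of the mean
length of the 21 vertebral edges of an image — normalizes errors across
image scales, giving ``NE_max`` / ``NE_mean`` and the interval histogram
with bins at integer multiples of ``E_a,i``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .landmarks import N_LANDMARKS, LandmarkSet

HISTOGRAM_BIN_LABELS = ("<=1", "<=2", "<=3", "<=4", "<=5", ">5")


def point_errors(
    detected: Sequence[LandmarkSet], truth: Sequence[LandmarkSet]
) -> np.ndarray:
    """``(N, 22)`` matrix of Euclidean point errors in pixels."""
    if len(detected) != len(truth):
        raise ValueError("detected and truth lists must have equal length")
    if not detected:
        raise ValueError("empty input")
    E = np.empty((len(detected), N_LANDMARKS))
    for i, (d, t) in enumerate(zip(detected, truth)):
        E[i] = np.linalg.norm(d.points - t.points, axis=1)
    return E


def summarize(E: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float, float]:
    """Per-image max/mean and their dataset averages ``(AE_max, AE_mean)``."""
    E = np.asarray(E, dtype=float)
    if E.ndim != 2 or E.size == 0:
        raise ValueError("E must be a non-empty (N, 22) matrix")
    e_max = E.max(axis=1)
    e_mean = E.mean(axis=1)
    return e_max, e_mean, float(e_max.mean()), float(e_mean.mean())


def allowable_error(landmarks: LandmarkSet) -> float:
    """20% of the mean of the 21 vertebral edge lengths.

    Edges: the four sides UL-UR, UL-LL, UR-LR, LL-LR of each of L1..L5, plus
    the S1 upper-endplate segment.
    """
    p = landmarks.points
    lengths = []
    for j in range(5):
        ul, ur, ll, lr = p[4 * j], p[4 * j + 1], p[4 * j + 2], p[4 * j + 3]
        lengths += [
            np.linalg.norm(ul - ur),
            np.linalg.norm(ul - ll),
            np.linalg.norm(ur - lr),
            np.linalg.norm(ll - lr),
        ]
    lengths.append(np.linalg.norm(p[20] - p[21]))
    return float(0.2 * np.mean(lengths))


def normalized_errors(
    e_max: np.ndarray, e_mean: np.ndarray, e_a: np.ndarray
) -> Tuple[float, float]:
    """``(NE_max, NE_mean)``: means of the per-image errors over ``E_a,i``."""
    e_a = np.asarray(e_a, dtype=float)
    if np.any(e_a <= 0):
        raise ValueError("all allowable errors must be positive")
    return float(np.mean(e_max / e_a)), float(np.mean(e_mean / e_a))


def interval_histogram(e_max: np.ndarray, e_a: np.ndarray) -> np.ndarray:
    """Counts of images with ``E_max,i`` in ``(k-1, k]·E_a,i`` for k = 1..5,
    plus an overflow bin ``> 5·E_a,i``. Upper bin edges are inclusive."""
    e_max = np.asarray(e_max, dtype=float)
    e_a = np.asarray(e_a, dtype=float)
    if e_max.shape != e_a.shape:
        raise ValueError("e_max and e_a must have equal length")
    ratio = e_max / e_a
    counts = np.zeros(6, dtype=int)
    for r in ratio:
        k = int(np.ceil(r)) if r > 0 else 1
        counts[min(k, 6) - 1] += 1
    return counts


class TTestResult(NamedTuple):
    t: float
    p: float
    degenerate: bool = False


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Two-sided paired-samples t-test on the differences ``a - b``.

    All-zero differences return ``p = 1`` with the degenerate flag; a
    zero-variance nonzero mean difference returns an infinite statistic with
    ``p = 0`` and the flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.shape[0] < 2:
        raise ValueError("need two equal-length samples with n >= 2")
    d = a - b
    if np.all(d == 0):
        return TTestResult(t=0.0, p=1.0, degenerate=True)
    if np.std(d, ddof=1) == 0:
        return TTestResult(t=float(np.sign(d.mean()) * np.inf), p=0.0, degenerate=True)
    res = stats.ttest_rel(a, b)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), degenerate=False)


def percent_change(before: float, after: float) -> float:
    """Relative change ``100 * (before - after) / before``."""
    if before == 0:
        raise ValueError("undefined percent change from zero")
    return 100.0 * (before - after) / before


@dataclass
class ErrorReport:
    """Full evaluation of a detection set against ground truth."""

    E_px: np.ndarray
    E_max_i: np.ndarray
    E_mean_i: np.ndarray
    AE_max: float
    AE_mean: float
    E_a_i: np.ndarray
    NE_max: float
    NE_mean: float
    histogram: np.ndarray
    unit: str = "px"

    @classmethod
    def evaluate(
        cls, detected: Sequence[LandmarkSet], truth: Sequence[LandmarkSet]
    ) -> "ErrorReport":
        """Compute every index. Errors are reported in millimetres when every
        ground-truth image carries a pixel spacing, otherwise in pixels."""
        E = point_errors(detected, truth)
        spacings = [t.pixel_spacing_mm for t in truth]
        unit = "px"
        scale = np.ones(len(truth))
        if all(s is not None for s in spacings):
            unit = "mm"
            scale = np.asarray(spacings, dtype=float)
        E_rep = E * scale[:, None]
        e_max, e_mean, ae_max, ae_mean = summarize(E_rep)
        e_a = np.array([allowable_error(t) for t in truth]) * scale
        ne_max, ne_mean = normalized_errors(e_max, e_mean, e_a)
        hist = interval_histogram(e_max, e_a)
        return cls(
            E_px=E,
            E_max_i=e_max,
            E_mean_i=e_mean,
            AE_max=ae_max,
            AE_mean=ae_mean,
            E_a_i=e_a,
            NE_max=ne_max,
            NE_mean=ne_mean,
            histogram=hist,
            unit=unit,
        )

    def to_dict(self) -> dict:
        return {
            "unit": self.unit,
            "AE_max": self.AE_max,
            "AE_mean": self.AE_mean,
            "NE_max": self.NE_max,
            "NE_mean": self.NE_mean,
            "E_max_i": self.E_max_i.tolist(),
            "E_mean_i": self.E_mean_i.tolist(),
            "E_a_i": self.E_a_i.tolist(),
            "histogram": {
                label: int(c) for label, c in zip(HISTOGRAM_BIN_LABELS, self.histogram)
            },
            "n_images": int(self.E_px.shape[0]),
        }

    def summary(self) -> str:
        lines = [
            f"Landmark detection error report ({self.unit})",
            f"  images:  {self.E_px.shape[0]}",
            f"  AE_max:  {self.AE_max:.4f} {self.unit}",
            f"  AE_mean: {self.AE_mean:.4f} {self.unit}",
            f"  NE_max:  {self.NE_max:.4f}",
            f"  NE_mean: {self.NE_mean:.4f}",
            "  E_max,i distribution over E_a,i intervals:",
            "    " + "  ".join(
                f"{label}: {c}" for label, c in zip(HISTOGRAM_BIN_LABELS, self.histogram)
            ),
        ]
        return "\n".join(lines)
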