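"""Statistical shape modelling: similarity alignment, generalized Procrustes
analysis, the PCA point-distribution model, and the shape-constraint
projection used inside the active-shape-model loop.

Conventions follow the classic point-distribution-model literature: the mean
shape is centred at the origin with unit Euclidean norm, similarity fits
exclude reflections, and shape coefficients may be clamped to
``±clamp_k·sqrt(lambda_k)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .landmarks import (
    SHAPE_DIM,
    N_LANDMARKS,
    LandmarkSet,
    points_to_vector,
    to_shape_vector,
    vector_to_points,
)

MAX_MODES = SHAPE_DIM - 1


class DegenerateShapeError(ValueError):
    """All points coincide or a projection denominator vanished."""


@dataclass(frozen=True)
class SimilarityTransform:
    """2D similarity transform ``p -> s·R(theta)·p + t`` (no reflection)."""

    scale: float
    rotation: float
    translation: np.ndarray

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an ``(n, 2)`` point array or a 44 shape vector."""
        arr = np.asarray(points, dtype=float)
        if arr.ndim == 1 and arr.shape[0] == SHAPE_DIM:
            return points_to_vector(self.apply(vector_to_points(arr)))
        return arr @ self.matrix.T + self.translation

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        inv_rot = -self.rotation
        c, s = np.cos(inv_rot), np.sin(inv_rot)
        mat = inv_scale * np.array([[c, -s], [s, c]])
        return SimilarityTransform(inv_scale, inv_rot, -(mat @ self.translation))

    @staticmethod
    def identity() -> "SimilarityTransform":
        return SimilarityTransform(1.0, 0.0, np.zeros(2))


def _as_points(shape: Union[np.ndarray, LandmarkSet]) -> np.ndarray:
    if isinstance(shape, LandmarkSet):
        return shape.points
    arr = np.asarray(shape, dtype=float)
    if arr.ndim == 1:
        return vector_to_points(arr)
    return arr


def fit_similarity(
    src: Union[np.ndarray, LandmarkSet],
    dst: Union[np.ndarray, LandmarkSet],
    weights: Optional[Sequence[float]] = None,
) -> SimilarityTransform:
    """Least-squares similarity transform mapping ``src`` onto ``dst``.

    Minimizes ``sum_i w_i * ||T(src_i) - dst_i||^2`` over scale > 0,
    rotation, and translation (reflections excluded), using the closed-form
    2D Procrustes solution.
    """
    a = _as_points(src)
    b = _as_points(dst)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] < 2:
        raise ValueError("src and dst must be matching (n>=2, 2) point arrays")
    if weights is None:
        w = np.ones(a.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (a.shape[0],) or np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be nonnegative, not all zero")
    wsum = w.sum()
    mu_a = (w[:, None] * a).sum(axis=0) / wsum
    mu_b = (w[:, None] * b).sum(axis=0) / wsum
    ac = a - mu_a
    bc = b - mu_b
    denom = float((w * (ac**2).sum(axis=1)).sum())
    if denom <= 0:
        raise DegenerateShapeError("all source points coincide")
    # s*cos, s*sin of the optimal rotation/scale
    dot = float((w * (ac * bc).sum(axis=1)).sum())
    cross = float((w * (ac[:, 0] * bc[:, 1] - ac[:, 1] * bc[:, 0])).sum())
    scale = np.hypot(dot, cross) / denom
    if scale <= 0:
        raise DegenerateShapeError("degenerate configuration: zero optimal scale")
    theta = np.arctan2(cross, dot)
    t = SimilarityTransform(scale, theta, np.zeros(2))
    translation = mu_b - t.apply(mu_a[None, :])[0]
    return SimilarityTransform(scale, theta, translation)


def _center_and_normalize(vec: np.ndarray) -> np.ndarray:
    pts = vector_to_points(vec)
    pts = pts - pts.mean(axis=0)
    v = points_to_vector(pts)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise DegenerateShapeError("degenerate shape: zero size")
    return v / norm


def _canonical_rotation(mean: np.ndarray) -> SimilarityTransform:
    """Rotation fixing the orientation gauge of a Procrustes mean.

    The mean of a GPA is defined only up to rotation; we pin it by rotating
    the dominant principal axis of the mean configuration onto +y (spines
    vertical), flipped so the first landmark block (L1) sits above the last
    (S1). Makes the mean independent of input ordering and of similarity
    pre-transforms of the inputs.
    """
    pts = vector_to_points(mean)
    cov = pts.T @ pts
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, int(np.argmax(evals))]
    angle = np.pi / 2 - np.arctan2(v[1], v[0])
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    rotated = pts @ rot.T
    if rotated[:4, 1].mean() > rotated[20:, 1].mean():
        angle += np.pi
    return SimilarityTransform(1.0, angle, np.zeros(2))


@dataclass
class GPAResult:
    aligned: np.ndarray  # (n, 44)
    mean: np.ndarray  # (44,)
    n_iterations: int
    converged: bool


def generalized_procrustes(
    shapes: Sequence[Union[np.ndarray, LandmarkSet]],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> GPAResult:
    """Generalized Procrustes analysis of a set of 22-point shapes.

    Iteratively aligns every shape to the running mean with a similarity
    transform and re-estimates the mean, which is kept centred at the origin
    with unit Euclidean norm and, on convergence, rotated to a canonical
    orientation (dominant principal axis along +y, L1 above S1).
    Non-convergence sets ``converged=False`` and emits a warning instead of
    failing.
    """
    vecs = [points_to_vector(_as_points(s)) for s in shapes]
    if len(vecs) < 2:
        raise ValueError("need at least two shapes")
    data = np.array(vecs)
    mean = _center_and_normalize(data[0])
    aligned = data.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(data.shape[0]):
            t = fit_similarity(data[i], mean)
            aligned[i] = t.apply(data[i])
        new_mean = _center_and_normalize(aligned.mean(axis=0))
        delta = np.linalg.norm(new_mean - mean)
        mean = new_mean
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"generalized Procrustes analysis did not converge in {max_iter} iterations",
            RuntimeWarning,
        )
    # fix the rotational gauge, then align against the canonical mean
    canon = _canonical_rotation(mean)
    mean = canon.apply(mean)
    for i in range(data.shape[0]):
        aligned[i] = fit_similarity(data[i], mean).apply(data[i])
    return GPAResult(aligned=aligned, mean=mean, n_iterations=it, converged=converged)


def tangent_project(vec: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Rescale shape(s) onto the hyperplane tangent to the unit sphere at ``mean``.

    ``v -> v / (v·mean)``; after projection the deviation from the mean is
    exactly orthogonal to the mean, linearizing shape statistics.
    """
    v = np.asarray(vec, dtype=float)
    denom = v @ mean
    if np.any(np.abs(denom) < 1e-12):
        raise DegenerateShapeError("tangent-plane projection degenerate")
    return v / (denom[..., None] if v.ndim > 1 else denom)


@dataclass
class ShapeModel:
    """Point-distribution model: mean shape plus principal modes of variation.

    Attributes
    ----------
    mean
        44-vector mean shape, centred at origin, unit norm.
    eigenvectors
        ``(44, K)`` orthonormal mode matrix, columns sorted by decreasing
        eigenvalue.
    eigenvalues
        Length-``K`` nonnegative variances, non-increasing.
    n_train
        Number of training shapes.
    metadata
        Free-form provenance (augmentation settings, seeds, ...).
    """

    mean: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    n_train: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.mean.shape != (SHAPE_DIM,):
            raise ValueError(f"mean must have length {SHAPE_DIM}")
        if self.eigenvectors.ndim != 2 or self.eigenvectors.shape[0] != SHAPE_DIM:
            raise ValueError(f"eigenvectors must be ({SHAPE_DIM}, K)")
        k = self.eigenvectors.shape[1]
        if self.eigenvalues.shape != (k,):
            raise ValueError("eigenvalues length must match eigenvector columns")
        if np.any(np.diff(self.eigenvalues) > 1e-12) or np.any(self.eigenvalues < -1e-12):
            raise ValueError("eigenvalues must be nonnegative and non-increasing")
        gram = self.eigenvectors.T @ self.eigenvectors
        if not np.allclose(gram, np.eye(k), atol=1e-10):
            raise ValueError("eigenvector columns must be orthonormal")
        centroid = vector_to_points(self.mean).mean(axis=0)
        if not (np.allclose(centroid, 0, atol=1e-10) and abs(np.linalg.norm(self.mean) - 1) < 1e-10):
            raise ValueError("mean shape must be centred at origin with unit norm")

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]

    @classmethod
    def fit(
        cls,
        shapes: Sequence[Union[np.ndarray, LandmarkSet]],
        tol: float = 1e-10,
        max_iter: int = 100,
        metadata: Optional[dict] = None,
    ) -> "ShapeModel":
        """Build the model: GPA alignment, tangent projection, then PCA.

        Aligned shapes are projected onto the tangent plane at the Procrustes
        mean before the eigendecomposition, so every retained mode is exactly
        orthogonal to the mean. All modes with positive eigenvalue (at most
        43) are retained; the number of modes actually used, ``n_P``, is
        chosen at fit time of the active shape model.
        """
        if len(shapes) < 3:
            raise ValueError("need at least three shapes to build a shape model")
        gpa = generalized_procrustes(shapes, tol=tol, max_iter=max_iter)
        projected = tangent_project(gpa.aligned, gpa.mean)
        dev = projected - gpa.mean
        cov = dev.T @ dev / (len(shapes) - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = evals[order]
        evecs = evecs[:, order]
        # retain positive-eigenvalue modes only (rank deficiency tolerated)
        cutoff = max(evals[0], 0.0) * 1e-12
        keep = min(int(np.sum(evals > cutoff)), MAX_MODES)
        evals = np.clip(evals[:keep], 0.0, None)
        evecs = evecs[:, :keep]
        # deterministic sign: largest-magnitude component positive
        for j in range(keep):
            idx = int(np.argmax(np.abs(evecs[:, j])))
            if evecs[idx, j] < 0:
                evecs[:, j] = -evecs[:, j]
        meta = dict(metadata or {})
        meta.setdefault("gpa_converged", gpa.converged)
        return cls(
            mean=gpa.mean,
            eigenvectors=evecs,
            eigenvalues=evals,
            n_train=len(shapes),
            metadata=meta,
        )

    def synthesize(self, b: np.ndarray) -> np.ndarray:
        """Shape vector ``mean + P[:, :len(b)] @ b`` in the model frame."""
        b = np.asarray(b, dtype=float)
        return self.mean + self.eigenvectors[:, : b.shape[0]] @ b

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "mean": self.mean.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "n_train": self.n_train,
            "created_by": "hasm",
            "augmentation": self.metadata.get("augmentation", {}),
            "metadata": {k: v for k, v in self.metadata.items() if k != "augmentation"},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "ShapeModel":
        payload = json.loads(Path(path).read_text())
        meta = dict(payload.get("metadata", {}))
        if payload.get("augmentation"):
            meta["augmentation"] = payload["augmentation"]
        return cls(
            mean=np.array(payload["mean"]),
            eigenvectors=np.array(payload["eigenvectors"]),
            eigenvalues=np.array(payload["eigenvalues"]),
            n_train=int(payload.get("n_train", 0)),
            metadata=meta,
        )


def build_shape_model(
    shapes: Sequence[Union[np.ndarray, LandmarkSet]], **kwargs
) -> ShapeModel:
    """Functional alias for :meth:`ShapeModel.fit`."""
    return ShapeModel.fit(shapes, **kwargs)


@dataclass
class ConstraintResult:
    X: np.ndarray  # constrained shape, image frame (44,)
    b: np.ndarray  # shape coefficients (n_P,)
    transform: SimilarityTransform
    n_iterations: int
    converged: bool


def constrain_shape(
    Y: np.ndarray,
    model: ShapeModel,
    n_P: int,
    clamp_k: Optional[float] = 3.0,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> ConstraintResult:
    """Project an image-frame shape onto the shape-model subspace.

    Alternates (i) synthesizing the model shape ``x = mean + P b``,
    (ii) fitting the pose ``T`` from ``x`` to ``Y``, (iii) mapping ``Y``
    into the model frame and projecting it onto the tangent plane at the
    mean (``y' = y / (y·mean)``), and (iv) re-estimating
    ``b = P^T (y' - mean)``, optionally clamped to ``±clamp_k·sqrt(lambda)``,
    until ``b`` stabilizes. Returns the constrained shape mapped back to the
    image frame.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.shape != (SHAPE_DIM,):
        raise ValueError(f"Y must be a length-{SHAPE_DIM} shape vector")
    if not 1 <= n_P <= model.n_modes:
        raise ValueError(f"n_P must be in 1..{model.n_modes}, got {n_P}")
    P = model.eigenvectors[:, :n_P]
    lam = model.eigenvalues[:n_P]
    limits = clamp_k * np.sqrt(lam) if clamp_k is not None else None
    b = np.zeros(n_P)
    transform = SimilarityTransform.identity()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        x = model.mean + P @ b
        transform = fit_similarity(x, Y)
        y = transform.inverse().apply(Y)
        denom = float(y @ model.mean)
        if abs(denom) < 1e-12:
            raise DegenerateShapeError(
                "tangent-plane projection degenerate: shape orthogonal to mean"
            )
        y_t = y / denom
        b_new = P.T @ (y_t - model.mean)
        if limits is not None:
            b_new = np.clip(b_new, -limits, limits)
        delta = np.linalg.norm(b_new - b)
        b = b_new
        if delta < tol:
            converged = True
            break
    x = model.mean + P @ b
    transform = fit_similarity(x, Y)
    X = transform.apply(x)
    return ConstraintResult(X=X, b=b, transform=transform, n_iterations=it, converged=converged)
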