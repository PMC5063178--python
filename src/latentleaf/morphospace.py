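"""Shape PCA on Procrustes-aligned coordinates: the eigenleaf morphospace.

After superimposition every leaf is a point in a 34-dimensional space of
flattened (x1, y1, …, x17, y17) coordinates. Principal components of the
covariance of these points are "eigenleaves": orthogonal directions of
shape variation, each visualizable as a deformation of the mean leaf at
± k standard deviations. Removing translation (2), rotation (1) and scale
(1) leaves at most 30 informative dimensions, so the trailing eigenvalues
of aligned 17-landmark data are numerically zero and are reported as
exactly zero.

Covariance (not correlation) PCA is used: all coordinates share units, the
standard convention in geometric morphometrics. Axis signs are fixed by
making each axis's largest-magnitude loading positive, so eigenleaves are
reproducible; the sign itself is arbitrary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .leafdata import N_LANDMARKS, LandmarkConfiguration
from .procrustes import AlignedShapes

#: eigenvalues below this fraction of the largest are the similarity-
#: transform null space and are reported as exactly zero
NULLSPACE_TOL = 1e-12


@dataclass
class Morphospace:
    """Mean shape, eigenleaf axes, and per-leaf scores."""

    mean_vector: np.ndarray  # (d,)
    axes: np.ndarray  # (d, d), rows are orthonormal eigenvectors
    eigenvalues: np.ndarray  # (d,), nonincreasing, >= 0
    scores: np.ndarray  # (n, d)
    leaf_ids: list[str] | None = None

    @property
    def variance_fraction(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total

    @property
    def rank(self) -> int:
        return int(np.count_nonzero(self.eigenvalues))

    # -- serialization ---------------------------------------------------

    def to_json(self, path) -> None:
        doc = {
            "mean_vector": self.mean_vector.tolist(),
            "axes": self.axes.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "leaf_ids": self.leaf_ids,
            "scores": self.scores.tolist(),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path) -> "Morphospace":
        doc = json.loads(Path(path).read_text())
        return cls(
            mean_vector=np.asarray(doc["mean_vector"], dtype=float),
            axes=np.asarray(doc["axes"], dtype=float),
            eigenvalues=np.asarray(doc["eigenvalues"], dtype=float),
            scores=np.asarray(doc["scores"], dtype=float),
            leaf_ids=doc.get("leaf_ids"),
        )

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        df = pd.DataFrame(self.scores, columns=cols)
        if self.leaf_ids is not None:
            df.insert(0, "leaf_id", self.leaf_ids)
        return df


def _flatten(aligned) -> np.ndarray:
    if isinstance(aligned, AlignedShapes):
        return aligned.flattened
    X = np.asarray(aligned, dtype=float)
    if X.ndim == 3:
        X = X.reshape(X.shape[0], -1)
    return X


def fit_pca(aligned) -> Morphospace:
    """Eigendecomposition (divisor n−1) of the flattened aligned coordinates."""
    X = _flatten(aligned)
    n = X.shape[0]
    if n < 2:
        raise ValidationError("PCA requires at least 2 leaves")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    axes = evecs[:, order].T  # rows are axes

    evals = np.clip(evals, 0.0, None)
    if evals[0] > 0:
        evals[evals < NULLSPACE_TOL * evals[0]] = 0.0
    # deterministic sign: largest-|loading| entry positive
    lead = np.argmax(np.abs(axes), axis=1)
    flip = axes[np.arange(axes.shape[0]), lead] < 0
    axes[flip] *= -1.0

    scores = Xc @ axes.T
    ids = aligned.leaf_ids if isinstance(aligned, AlignedShapes) else None
    return Morphospace(mean_vector=mean, axes=axes, eigenvalues=evals, scores=scores, leaf_ids=ids)


def project(space: Morphospace, aligned_new) -> np.ndarray:
    """Scores of new leaves on an existing space (which is left unchanged).

    The new leaves must be superimposed in the same frame (same consensus)
    as the leaves the space was fit to.
    """
    X = _flatten(aligned_new)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != space.mean_vector.shape[0]:
        raise ValidationError(
            f"dimension mismatch: space is {space.mean_vector.shape[0]}-dimensional, "
            f"data is {X.shape[1]}-dimensional"
        )
    return (X - space.mean_vector) @ space.axes.T


def eigenleaf(space: Morphospace, axis_index: int, k_sd: float) -> LandmarkConfiguration:
    """The mean shape deformed ``k_sd`` standard deviations along one axis."""
    if not 0 <= axis_index < space.axes.shape[0]:
        raise ValidationError(f"axis_index {axis_index} out of range")
    lam = space.eigenvalues[axis_index]
    if lam <= 0:
        raise ValidationError(f"axis {axis_index} has zero variance; no eigenleaf exists")
    vec = space.mean_vector + k_sd * np.sqrt(lam) * space.axes[axis_index]
    return LandmarkConfiguration(vec.reshape(N_LANDMARKS, 2))
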