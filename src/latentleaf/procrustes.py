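"""Ordinary and generalized Procrustes superimposition.

Landmark configurations differ by nuisance similarity transforms —
translation, scale, rotation, and (for leaves scanned abaxial side up in
arbitrary orientation) reflection. Superimposition removes these so that
only shape differences remain.

The pairwise kernel is the classical orthogonal (Kabsch) solution: after
centering and unit-centroid-size scaling, the rotation minimizing the
residual sum of squares comes from the singular decomposition of the
cross-covariance; constraining the determinant to +1 forbids reflection.

Generalized Procrustes analysis (GPA) iterates the kernel against a running
consensus: all configurations are centered (and, by default, scaled to unit
centroid size), each is rotated onto the consensus, and the consensus is
recomputed as the re-normalized arithmetic mean, until the consensus stops
moving. Both steps are exact minimizers, so the summed squared distance to
the consensus is nonincreasing across iterations.

With scaling on, GPA finishes by rescaling every configuration onto the
tangent hyperplane at the consensus (<X, consensus> = 1). This replaces the
curved unit-size constraint with a linear one, so the aligned coordinates
span an exactly 30-dimensional affine subspace (34 coordinates minus two
translations, one rotation, one scale) and downstream PCA sees no spurious
curvature dimension; centroid sizes of aligned configurations equal 1 up to
second order in Procrustes distance.

The rotational frame left over after GPA is arbitrary; for reproducibility
the whole aligned set is rotated so the consensus petiole-to-midvein-tip
axis (landmark 1 → landmark 2) points along +y, and — when reflection was
allowed, so that the input chirality carries no information — reflected, if
needed, to a fixed consensus chirality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConvergenceError, DegenerateConfigurationError, ValidationError
from .leafdata import (
    N_LANDMARKS,
    WIDE_COORD_COLUMNS,
    LandmarkConfiguration,
    LeafDataset,
)


def _coords(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return np.asarray(config.coords, dtype=float)
    return np.asarray(config, dtype=float)


def centroid_size(config) -> float:
    """Square root of the summed squared landmark distances to the centroid."""
    c = _coords(config)
    centered = c - c.mean(axis=0)
    size = float(np.sqrt((centered**2).sum()))
    if size == 0.0:
        raise DegenerateConfigurationError("all landmarks coincide; centroid size is 0")
    return size


def _optimal_maps(M: np.ndarray, allow_reflection: bool) -> np.ndarray:
    """Batched optimal orthogonal maps from (n, 2, 2) cross-covariances.

    Returns Q maximizing trace(Qᵀ M); det(Q) = −1 permitted iff
    ``allow_reflection``, otherwise the smallest singular value is flipped.
    """
    U, _, Vt = np.linalg.svd(M)
    Q = U @ Vt
    if not allow_reflection:
        neg = np.linalg.det(Q) < 0
        if np.any(neg):
            U = U.copy()
            U[neg, :, -1] *= -1.0
            Q[neg] = U[neg] @ Vt[neg]
    return Q


def superimpose_pair(
    a,
    b,
    allow_reflection: bool = True,
    scale: bool = True,
):
    """Optimally map ``b`` onto ``a``; return (transformed b, Procrustes distance).

    The transformed configuration is ``b`` translated, rotated (orthogonal
    map with determinant −1 permitted iff ``allow_reflection``) and, when
    ``scale``, rescaled by least squares into ``a``'s frame. The distance is
    the residual root-sum-of-squares after both configurations are centered
    and scaled to unit centroid size — zero iff the two are similar (up to
    the allowed transforms).
    """
    A, B = _coords(a), _coords(b)
    if A.shape != B.shape:
        raise ValidationError(f"landmark-count mismatch: {A.shape} vs {B.shape}")
    a_mean, b_mean = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - a_mean, B - b_mean
    sa, sb = centroid_size(A), centroid_size(B)
    An, Bn = Ac / sa, Bc / sb

    Q = _optimal_maps((Bn.T @ An)[None], allow_reflection)[0]
    distance = float(np.sqrt(((An - Bn @ Q) ** 2).sum()))

    if scale:
        beta = float(np.trace(Q.T @ Bc.T @ Ac) / (Bc**2).sum())
    else:
        beta = 1.0
    transformed = beta * (Bc @ Q) + a_mean
    if isinstance(b, LandmarkConfiguration):
        transformed = LandmarkConfiguration(transformed)
    return transformed, distance


@dataclass
class AlignedShapes:
    """Superimposed configurations and the consensus they were fit to."""

    aligned: np.ndarray  # (n, 17, 2)
    mean_shape: np.ndarray  # (17, 2), unit centroid size
    centroid_sizes: np.ndarray  # (n,) original sizes
    n_iter: int
    final_delta: float
    leaf_ids: list[str] | None = None
    objective_trace: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return self.aligned.shape[0]

    @property
    def flattened(self) -> np.ndarray:
        """(n, 34) view in (x1, y1, x2, y2, …) order."""
        return self.aligned.reshape(len(self), -1)


def _orientation_fix(aligned: np.ndarray, consensus: np.ndarray, fix_chirality: bool):
    """Rotate the set so consensus landmark 1→2 points along +y; optionally
    reflect to a fixed chirality (positive signed-area functional)."""
    v = consensus[1] - consensus[0]
    norm = float(np.hypot(*v))
    if norm > 0:
        ux, uy = v / norm
        G = np.array([[uy, ux], [-ux, uy]])  # row-vector rotation: v @ G = (0, |v|)
        aligned = aligned @ G
        consensus = consensus @ G
    if fix_chirality:
        x, y = consensus[:, 0], consensus[:, 1]
        signed = float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        if signed < 0:
            aligned = aligned * np.array([-1.0, 1.0])
            consensus = consensus * np.array([-1.0, 1.0])
    return aligned, consensus


def gpa(
    dataset,
    allow_reflection: bool = True,
    scale: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedShapes:
    """Generalized Procrustes analysis of a dataset (or (n, k, 2) array).

    Raises :class:`ConvergenceError` (carrying the final consensus change)
    if the consensus is still moving after ``max_iter`` iterations, and
    names the offending leaf for degenerate configurations.
    """
    if isinstance(dataset, LeafDataset):
        X = dataset.coords_array().copy()
        ids = dataset.leaf_ids()
    else:
        X = np.asarray(dataset, dtype=float).copy()
        ids = None
    n = X.shape[0]
    if n < 2:
        raise ValidationError("GPA requires at least 2 configurations")

    X -= X.mean(axis=1, keepdims=True)
    sizes = np.sqrt((X**2).sum(axis=(1, 2)))
    bad = np.flatnonzero(sizes == 0)
    if bad.size:
        who = ids[bad[0]] if ids else f"index {bad[0]}"
        raise DegenerateConfigurationError(f"degenerate configuration: {who}")
    if scale:
        X /= sizes[:, None, None]

    consensus = X[0] / np.sqrt((X[0] ** 2).sum())
    delta = np.inf
    trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        Q = _optimal_maps(np.swapaxes(X, 1, 2) @ consensus, allow_reflection)
        X = X @ Q
        mean = X.mean(axis=0)
        mean -= mean.mean(axis=0)
        msize = np.sqrt((mean**2).sum())
        if msize == 0:
            raise DegenerateConfigurationError("consensus collapsed to a point")
        new_consensus = mean / msize
        delta = float(np.sqrt(((new_consensus - consensus) ** 2).sum()))
        consensus = new_consensus
        trace.append(float(((X - consensus) ** 2).sum()))
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"GPA did not converge in {max_iter} iterations (last change {delta:.3e})",
            final_delta=delta,
        )

    if scale:
        # Finishing step: rescale each configuration onto the tangent
        # hyperplane {X : <X, consensus> = 1}. Unit-centroid-size scaling
        # constrains shapes to a sphere, whose curvature leaks a spurious
        # 31st dimension of variance into the aligned coordinates; the
        # hyperplane constraint is linear, so together with the exact
        # centering and rotation-optimality constraints the aligned set
        # spans an exactly 30-dimensional affine subspace. Sizes deviate
        # from 1 only at second order in Procrustes distance.
        radial = X.reshape(n, -1) @ consensus.reshape(-1)
        X = X / radial[:, None, None]
        mean = X.mean(axis=0)
        mean -= mean.mean(axis=0)
        consensus = mean / np.sqrt((mean**2).sum())

    X, consensus = _orientation_fix(X, consensus, fix_chirality=allow_reflection)
    return AlignedShapes(
        aligned=X,
        mean_shape=consensus,
        centroid_sizes=sizes,
        n_iter=n_iter,
        final_delta=delta,
        leaf_ids=ids,
        objective_trace=trace,
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

ALIGNED_COORD_COLUMNS = [f"aligned_{c}" for c in WIDE_COORD_COLUMNS]


def write_aligned_csv(aligned: AlignedShapes, path, dataset: LeafDataset | None = None) -> None:
    """Aligned coordinates in the wide dialect with an ``aligned_`` prefix.

    When the source dataset is supplied its metadata columns are carried
    along, so classifier stages can be run straight off the file.
    """
    flat = aligned.flattened
    df = pd.DataFrame(flat, columns=ALIGNED_COORD_COLUMNS)
    df.insert(0, "centroid_size", aligned.centroid_sizes)
    if dataset is not None:
        meta = dataset.metadata_frame()
        if len(meta) != len(df):
            raise ValidationError("dataset does not match aligned shapes in length")
        df = pd.concat([meta, df], axis=1)
    elif aligned.leaf_ids is not None:
        df.insert(0, "leaf_id", aligned.leaf_ids)
    df.to_csv(Path(path), index=False)


def read_aligned_csv(path) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a file written by :func:`write_aligned_csv`.

    Returns (metadata frame, (n, 17, 2) aligned coordinates).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ALIGNED_COORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: not an aligned-coordinates file (missing {missing[:3]})")
    coords = df[ALIGNED_COORD_COLUMNS].to_numpy(dtype=float).reshape(-1, N_LANDMARKS, 2)
    meta = df.drop(columns=ALIGNED_COORD_COLUMNS)
    return meta, coords


def write_consensus_csv(aligned: AlignedShapes, path) -> None:
    """The consensus (mean) shape as a single wide-format row."""
    flat = aligned.mean_shape.reshape(1, -1)
    pd.DataFrame(flat, columns=WIDE_COORD_COLUMNS).to_csv(
        Path(path), index=False
    )
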