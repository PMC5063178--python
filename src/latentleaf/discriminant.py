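"""Latent-shape discriminants: LDA on Procrustes-aligned coordinates.

A linear discriminant analysis fit to aligned leaf coordinates isolates the
multivariate shape signature ("latent shape") that best separates one
factor — species identity, developmental stage Sn, or leaf number Ln —
while ignoring the others. Reallocating each leaf to its *apparent* class
under the fitted discriminants, and cross-tabulating actual against
apparent classes, measures how much shape information each factor carries;
the same machinery run with a reference collection as training set stages
leaves from another collection onto the reference developmental axis.

Procrustes coordinates are rank-deficient (the similarity transforms remove
four degrees of freedom), so the data are first reduced to the PCA sub-basis
with nonnegligible variance; the Gaussian equal-covariance discriminant is
then fit in that full-rank space, with a small ridge guard on the pooled
covariance. Stage and leaf-number classes are treated as unordered
categories — ordinality enters only afterwards, through the apparent-minus-
actual arithmetic of the heterochrony module.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

from .errors import ValidationError
from .leafdata import LeafDataset, select_positions
from .morphospace import _flatten
from .procrustes import gpa


@dataclass
class DiscriminantModel:
    """Gaussian equal-covariance discriminants in a reduced PCA basis."""

    class_labels: list  # ordered
    priors: np.ndarray  # (g,), sums to 1
    class_means: np.ndarray  # (g, r) in the reduced basis
    pooled_covariance: np.ndarray  # (r, r), SPD after ridge
    reduction_mean: np.ndarray  # (d,)
    reduction_basis: np.ndarray  # (r, d), rows orthonormal
    target_kind: str = "species"

    def reduce(self, X: np.ndarray) -> np.ndarray:
        return (X - self.reduction_mean) @ self.reduction_basis.T

    def to_json(self, path) -> None:
        doc = {
            "class_labels": [str(c) for c in self.class_labels],
            "label_dtype": "int" if all(
                isinstance(c, (int, np.integer)) for c in self.class_labels
            ) else "str",
            "priors": self.priors.tolist(),
            "class_means": self.class_means.tolist(),
            "pooled_covariance": self.pooled_covariance.tolist(),
            "reduction_mean": self.reduction_mean.tolist(),
            "reduction_basis": self.reduction_basis.tolist(),
            "target_kind": self.target_kind,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path) -> "DiscriminantModel":
        doc = json.loads(Path(path).read_text())
        cast = int if doc.get("label_dtype") == "int" else str
        return cls(
            class_labels=[cast(c) for c in doc["class_labels"]],
            priors=np.asarray(doc["priors"], dtype=float),
            class_means=np.asarray(doc["class_means"], dtype=float),
            pooled_covariance=np.asarray(doc["pooled_covariance"], dtype=float),
            reduction_mean=np.asarray(doc["reduction_mean"], dtype=float),
            reduction_basis=np.asarray(doc["reduction_basis"], dtype=float),
            target_kind=doc["target_kind"],
        )


def fit_lda(
    aligned,
    labels,
    prior_mode: str = "proportional",
    rank_tol: float = 1e-8,
    ridge: float = 1e-8,
    target_kind: str = "species",
) -> DiscriminantModel:
    """Fit latent-shape discriminants for a per-leaf categorical factor.

    ``aligned`` may be an :class:`AlignedShapes` or any (n, d) array.
    Classes are ordered by first appearance for string labels and
    numerically for integer labels; every class needs at least 2 members.
    Priors are class-frequency proportional by default, or ``uniform``.
    """
    X = _flatten(aligned)
    labels = list(labels)
    if len(labels) != X.shape[0]:
        raise ValidationError("labels and aligned shapes differ in length")
    if prior_mode not in ("proportional", "uniform"):
        raise ValueError(f"unknown prior_mode {prior_mode!r}")

    if all(isinstance(c, (int, np.integer)) for c in labels):
        class_labels = sorted(set(int(c) for c in labels))
    else:
        class_labels = list(dict.fromkeys(labels))
    g = len(class_labels)
    if g < 2:
        raise ValidationError("LDA requires at least 2 classes")
    idx = {c: k for k, c in enumerate(class_labels)}
    y = np.array([idx[c] for c in labels])
    counts = np.bincount(y, minlength=g)
    small = [class_labels[k] for k in np.flatnonzero(counts < 2)]
    if small:
        raise ValidationError(f"classes with fewer than 2 members: {small}")

    # rank reduction: PCA sub-basis with eigenvalue > rank_tol * max
    n = X.shape[0]
    mu = X.mean(axis=0)
    Xc = X - mu
    cov = (Xc.T @ Xc) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > rank_tol * max(evals[0], 0.0)
    if not keep.any():
        raise ValidationError("data have no variance; cannot fit discriminants")
    basis = evecs[:, keep].T
    Z = Xc @ basis.T
    r = Z.shape[1]

    means = np.stack([Z[y == k].mean(axis=0) for k in range(g)])
    resid = Z - means[y]
    Sw = (resid.T @ resid) / (n - g)
    Sw = Sw + ridge * (np.trace(Sw) / r) * np.eye(r)
    try:
        cho_factor(Sw)
    except np.linalg.LinAlgError as e:  # pragma: no cover - ridge guard normally suffices
        raise ValidationError(
            "pooled within-class covariance is singular after reduction and ridge"
        ) from e

    if prior_mode == "proportional":
        priors = counts / counts.sum()
    else:
        priors = np.full(g, 1.0 / g)

    return DiscriminantModel(
        class_labels=class_labels,
        priors=priors,
        class_means=means,
        pooled_covariance=Sw,
        reduction_mean=mu,
        reduction_basis=basis,
        target_kind=target_kind,
    )


def predict_classes(model: DiscriminantModel, aligned):
    """Reallocate leaves to apparent classes under the fitted discriminants.

    Returns (apparent labels, posterior DataFrame with one column per
    class). Posterior rows sum to 1; ties in the argmax break to the first
    class in model order.
    """
    X = _flatten(aligned)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.reduction_mean.shape[0]:
        raise ValidationError(
            f"dimension mismatch: model expects {model.reduction_mean.shape[0]} "
            f"coordinates, got {X.shape[1]}"
        )
    Z = model.reduce(X)
    c, low = cho_factor(model.pooled_covariance)
    Sinv_mu = cho_solve((c, low), model.class_means.T)  # (r, g)
    # log-discriminant: x Σ⁻¹ μ_k − ½ μ_k Σ⁻¹ μ_k + log π_k (quadratic term common)
    lin = Z @ Sinv_mu
    const = -0.5 * np.sum(model.class_means * Sinv_mu.T, axis=1) + np.log(model.priors)
    logpost = lin + const
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    post = np.exp(logpost)
    apparent_idx = np.argmax(post, axis=1)
    apparent = [model.class_labels[k] for k in apparent_idx]
    post_df = pd.DataFrame(post, columns=[str(c_) for c_ in model.class_labels])
    return apparent, post_df


@dataclass
class ConfusionMatrix:
    """Actual-vs-apparent cross-tabulation with row-normalized proportions."""

    labels: list
    counts: np.ndarray  # (g, g) ints, indexed (actual, apparent)
    proportions: np.ndarray = field(init=False)

    def __post_init__(self):
        counts = np.asarray(self.counts)
        rowsums = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            props = np.where(rowsums > 0, counts / rowsums, np.nan)
        self.proportions = props

    @property
    def per_class_accuracy(self) -> np.ndarray:
        return np.diag(self.proportions)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)

    def proportions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.proportions, index=self.labels, columns=self.labels)


def confusion(actual, apparent, labels=None) -> ConfusionMatrix:
    """Cross-tabulate actual against apparent class labels."""
    actual, apparent = list(actual), list(apparent)
    if len(actual) != len(apparent):
        raise ValidationError("actual and apparent label lists differ in length")
    if not actual:
        raise ValidationError("cannot build a confusion matrix from no leaves")
    if labels is None:
        seen = list(dict.fromkeys(actual)) + [c for c in dict.fromkeys(apparent) if c not in actual]
        if all(isinstance(c, (int, np.integer)) for c in seen):
            labels = sorted(set(int(c) for c in seen))
        else:
            labels = seen
    idx = {c: k for k, c in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for a, p in zip(actual, apparent):
        counts[idx[a], idx[p]] += 1
    return ConfusionMatrix(labels=list(labels), counts=counts)


def cross_stage(
    train: LeafDataset,
    test: LeafDataset,
    target_kind: str = "leaf_number",
    window: tuple[int, int] = (1, 10),
    prior_mode: str = "proportional",
    mode: str = "joint",
    allow_reflection: bool = True,
    restrict_test: bool = False,
) -> pd.DataFrame:
    """Stage one collection's leaves on another collection's developmental axis.

    The training dataset is restricted to the Sn (``target_kind='stage'``)
    or Ln (``'leaf_number'``) window; by default one joint GPA is run over
    training + test leaves together (``mode='project'`` instead aligns the
    test leaves one by one onto the train-only consensus); discriminants
    are fit on the training rows with the integer node values as classes;
    apparent integer values are returned for every test leaf.

    Returns a frame with leaf_id, vine_id, species, actual, apparent and
    posterior_max columns for the test rows. Training classes with fewer
    than 2 leaves are dropped with a warning. ``restrict_test`` windows the
    test collection too (off by default: every test leaf is staged, with
    apparent values necessarily inside the trained window).
    """
    if target_kind not in ("stage", "leaf_number"):
        raise ValueError(f"target_kind must be 'stage' or 'leaf_number', got {target_kind!r}")
    lo, hi = window
    sel_mode = "stage_window" if target_kind == "stage" else "leafnum_window"
    train_w = select_positions(train, sel_mode, lo=lo, hi=hi)
    if len(train_w) == 0:
        raise ValidationError(f"no training leaves inside the window {window}")
    if restrict_test:
        test = select_positions(test, sel_mode, lo=lo, hi=hi)

    train_labels = [getattr(r, target_kind) for r in train_w]
    counts = pd.Series(train_labels).value_counts()
    small = sorted(counts.index[counts < 2])
    if small:
        warnings.warn(
            f"dropping training classes with < 2 leaves: {small}", stacklevel=2
        )
        keep_ids = [
            r.leaf_id for r in train_w if getattr(r, target_kind) not in set(small)
        ]
        train_w = train_w.subset(keep_ids)
        train_labels = [getattr(r, target_kind) for r in train_w]
    if len(set(train_labels)) < 2:
        raise ValidationError("fewer than 2 usable training classes remain")

    n_train = len(train_w)
    if mode == "joint":
        combined = np.concatenate([train_w.coords_array(), test.coords_array()])
        aligned = gpa(combined, allow_reflection=allow_reflection)
        X_train = aligned.flattened[:n_train]
        X_test = aligned.flattened[n_train:]
    elif mode == "project":
        aligned_train = gpa(train_w.coords_array(), allow_reflection=allow_reflection)
        X_train = aligned_train.flattened
        from .procrustes import superimpose_pair  # local: avoids polluting module API

        fitted = [
            superimpose_pair(aligned_train.mean_shape, cfg, allow_reflection=allow_reflection)[0]
            for cfg in test.coords_array()
        ]
        X_test = np.stack(fitted).reshape(len(test), -1)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    model = fit_lda(X_train, train_labels, prior_mode=prior_mode, target_kind=target_kind)
    apparent, post = predict_classes(model, X_test)
    meta = test.metadata_frame()
    return pd.DataFrame(
        {
            "leaf_id": meta["leaf_id"],
            "vine_id": meta["vine_id"],
            "species": meta["species"],
            "actual": meta[target_kind].astype(int),
            "apparent": np.asarray(apparent, dtype=int),
            "posterior_max": post.to_numpy().max(axis=1),
        }
    )
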