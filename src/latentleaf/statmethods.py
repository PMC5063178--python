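"""Rank statistics, FDR control, and correlation-distance clustering.

The statistical toolkit behind the morphometric pipeline: Spearman's rank
correlation (midranks for ties; exact permutation p-value for n ≤ 8, t
approximation above), the Kruskal–Wallis rank test, Benjamini–Hochberg
step-up FDR adjustment, pairwise-complete Spearman correlation matrices
over trait tables, and agglomerative clustering on 1 − r correlation
distances with newick export for tree viewers.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage as _scipy_linkage

from .errors import ValidationError

#: largest n for which the Spearman permutation null is enumerated exactly
EXACT_PERM_MAX_N = 8


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    if denom == 0:
        raise ValidationError("constant input: Spearman's rho is undefined")
    return float((rxc * ryc).sum() / denom)


def spearman(x, y) -> tuple[float, float]:
    """Spearman's rho with midranks for ties, and a two-tailed p-value.

    Pairs with missing values are dropped. The p-value enumerates the
    permutation null exactly for n ≤ 8 and otherwise uses the t
    approximation t = rho·sqrt((n−2)/(1−rho²)) on n−2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("spearman requires two equal-length vectors")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValidationError(f"spearman requires at least 3 complete pairs, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rho_from_ranks(rx, ry)

    if n <= EXACT_PERM_MAX_N:
        obs = abs(rho) - 1e-12
        hits = total = 0
        for perm in permutations(ry):
            total += 1
            if abs(_rho_from_ranks(rx, np.asarray(perm))) >= obs:
                hits += 1
        p = hits / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def kruskal_wallis(values, groups) -> tuple[float, int, float]:
    """Tie-corrected Kruskal–Wallis H with df = g − 1 and chi-square p."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValidationError("values and groups differ in length")
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValidationError("Kruskal–Wallis requires at least 2 groups")
    samples = [values[groups == g] for g in uniq]
    if any(len(s) == 0 for s in samples):
        raise ValidationError("every group needs at least one value")
    if np.ptp(values) == 0:
        raise ValidationError("Kruskal–Wallis undefined: all values are tied across groups")
    try:
        H, p = stats.kruskal(*samples)
    except ValueError as e:  # scipy: all numbers identical
        raise ValidationError(f"Kruskal–Wallis undefined: {e}") from e
    return float(H), len(uniq) - 1, float(p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q_(i) = min over j ≥ i of p_(j)·m/j over the ascending-sorted values,
    capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1-d vector of p-values")
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class CorrelationResult:
    """Pairwise-complete Spearman correlations with BH-adjusted p-values."""

    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    n: pd.DataFrame  # complete pairs used per cell


def corr_matrix(table: pd.DataFrame, min_pairs: int = 4) -> CorrelationResult:
    """Spearman correlation of every column pair over pairwise-complete rows.

    Pairs with fewer than ``min_pairs`` complete observations (or a
    constant vector) are reported as missing. BH adjustment is applied
    jointly across all defined off-diagonal p-values.
    """
    if table.columns.duplicated().any():
        raise ValidationError("trait table column names must be unique")
    cols = list(table.columns)
    k = len(cols)
    if k < 2:
        raise ValidationError("correlation matrix requires at least 2 columns")
    X = table.to_numpy(dtype=float)
    rho = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    nmat = np.zeros((k, k), dtype=int)
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(nmat, np.isfinite(X).sum(axis=0))
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            ok = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
            nmat[i, j] = nmat[j, i] = int(ok.sum())
            if ok.sum() < min_pairs:
                continue
            try:
                r_ij, p_ij = spearman(X[ok, i], X[ok, j])
            except ValidationError:
                continue  # constant within the complete pairs
            rho[i, j] = rho[j, i] = r_ij
            p[i, j] = p[j, i] = p_ij
            pairs.append((i, j))
    q = np.full((k, k), np.nan)
    if pairs:
        raw = np.array([p[i, j] for i, j in pairs])
        adj = bh_adjust(raw)
        for (i, j), v in zip(pairs, adj):
            q[i, j] = q[j, i] = v
    as_df = lambda M, dtype=float: pd.DataFrame(M, index=cols, columns=cols)  # noqa: E731
    return CorrelationResult(rho=as_df(rho), p=as_df(p), q=as_df(q), n=as_df(nmat))


# ---------------------------------------------------------------------------
# hierarchical clustering on correlation distance
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Agglomerative merge history over labelled leaves.

    ``merges[i] = (a, b)`` joins clusters a and b at ``heights[i]``;
    cluster ids 0..n−1 are leaves (in ``labels`` order), id n+i is the
    cluster formed by merge i.
    """

    labels: list[str]
    merges: np.ndarray  # (n-1, 2) int
    heights: np.ndarray  # (n-1,) nondecreasing

    def __post_init__(self):
        n = len(self.labels)
        if self.merges.shape != (n - 1, 2):
            raise ValidationError("a dendrogram over n leaves requires n-1 merges")
        if np.any(np.diff(self.heights) < -1e-12):
            raise ValidationError("merge heights must be nondecreasing")


def hcluster(
    table,
    distance: str = "one_minus_r",
    method: str = "complete",
    correlation: str = "spearman",
) -> Dendrogram:
    """Cluster trait columns (or named vectors) on correlation distance.

    ``table`` is a DataFrame whose columns are the items, or a mapping of
    name → vector. d(i, j) = 1 − r(i, j) with r computed on pairwise-
    complete observations (Spearman by default, Pearson optional);
    linkage is complete, average or single.
    """
    if isinstance(table, dict):
        table = pd.DataFrame(table)
    if distance != "one_minus_r":
        raise ValueError(f"unknown distance {distance!r}")
    if method not in ("complete", "average", "single"):
        raise ValueError(f"unknown linkage {method!r}")
    cols = list(table.columns)
    k = len(cols)
    if k < 2:
        raise ValidationError("clustering requires at least 2 items")
    X = table.to_numpy(dtype=float)
    condensed = []
    for i in range(k):
        for j in range(i + 1, k):
            ok = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
            xi, xj = X[ok, i], X[ok, j]
            if len(xi) < 2 or np.ptp(xi) == 0 or np.ptp(xj) == 0:
                raise ValidationError(
                    f"correlation between {cols[i]!r} and {cols[j]!r} is undefined "
                    "(insufficient complete observations or constant values)"
                )
            if correlation == "spearman":
                r = _rho_from_ranks(stats.rankdata(xi), stats.rankdata(xj))
            elif correlation == "pearson":
                r = _rho_from_ranks(xi, xj)  # same centered formula on raw values
            else:
                raise ValueError(f"unknown correlation {correlation!r}")
            condensed.append(1.0 - r)
    Z = _scipy_linkage(np.asarray(condensed), method=method)
    return Dendrogram(
        labels=[str(c) for c in cols],
        merges=Z[:, :2].astype(int),
        heights=np.maximum(Z[:, 2], 0.0),
    )


_NEWICK_META = set("(),:;'\" \t[]")


def _quote(label: str) -> str:
    if any(ch in _NEWICK_META for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(d: Dendrogram) -> str:
    """Serialize a dendrogram to newick; branch length = parent merge
    height − child merge height, leaves at height 0."""
    n = len(d.labels)

    def height(node: int) -> float:
        return 0.0 if node < n else float(d.heights[node - n])

    def render(node: int, parent_height: float) -> str:
        bl = parent_height - height(node)
        if node < n:
            return f"{_quote(d.labels[node])}:{bl:.12g}"
        a, b = d.merges[node - n]
        inner = f"({render(int(a), height(node))},{render(int(b), height(node))})"
        return f"{inner}:{bl:.12g}"

    root = n + len(d.heights) - 1
    a, b = d.merges[-1]
    h = height(root)
    return f"({render(int(a), h)},{render(int(b), h)});"


def write_newick(d: Dendrogram, path) -> None:
    Path(path).write_text(to_newick(d) + "\n")
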