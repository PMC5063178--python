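"""Heterochrony statistics from classifier-staged leaves.

When a shape classifier reallocates a leaf to an *apparent* developmental
stage or leaf number, the signed offset ``apparent − actual`` (in nodes)
says how far ahead (+) or behind (−) of its true shoot position the leaf
appears, developmentally speaking. Averaging these relative values per
vine, then testing each species' vine means against zero, detects taxa
whose leaf development is precociously advanced or lagging — heterochrony.
A second, independent marker of premature heteroblastic change is the first
node (counted from the shoot base) whose opposite organ is a tendril rather
than a flower cluster; its correlation with the per-vine mean relative leaf
number links the two measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .leafdata import LeafDataset
from .statmethods import bh_adjust, spearman


def relative_values(actual, apparent) -> np.ndarray:
    """Element-wise apparent − actual, in signed nodes.

    E.g. an S5 leaf staged as S7 is +2 (ahead); an L4 leaf staged as L2
    is −2 (behind).
    """
    a = np.asarray(actual)
    p = np.asarray(apparent)
    if a.shape != p.shape:
        raise ValidationError("actual and apparent differ in length")
    for arr, name in ((a, "actual"), (p, "apparent")):
        if not np.issubdtype(arr.dtype, np.integer):
            as_float = arr.astype(float)
            if not np.all(as_float == np.round(as_float)):
                raise ValidationError(f"{name} values must be integers")
    return p.astype(int) - a.astype(int)


def vine_means(relatives, vine_ids) -> pd.DataFrame:
    """Arithmetic mean relative value per vine (columns: vine_id,
    mean_relative, n_leaves)."""
    rel = np.asarray(relatives, dtype=float)
    vines = list(vine_ids)
    if len(vines) != rel.shape[0]:
        raise ValidationError("relatives and vine ids differ in length")
    df = pd.DataFrame({"vine_id": vines, "relative": rel})
    out = (
        df.groupby("vine_id", sort=False)["relative"]
        .agg(mean_relative="mean", n_leaves="count")
        .reset_index()
    )
    out["n_leaves"] = out["n_leaves"].astype(int)
    return out


def species_offsets(per_vine: pd.DataFrame, adjust: bool = False) -> pd.DataFrame:
    """One-sample two-tailed t-tests of per-species vine means against zero.

    ``per_vine`` needs vine_id, species, mean_relative columns. Species with
    fewer than 3 vines or zero variance of vine means get no test and a
    reason code instead. With ``adjust``, BH-adjusted p-values are reported
    side by side (the raw p is always present).
    """
    required = {"vine_id", "species", "mean_relative"}
    if not required.issubset(per_vine.columns):
        raise ValidationError(f"per_vine frame requires columns {sorted(required)}")
    rows = []
    for sp, grp in per_vine.groupby("species", sort=False):
        vals = grp["mean_relative"].to_numpy(dtype=float)
        n = len(vals)
        row = {
            "species": sp,
            "mean_of_vine_means": float(vals.mean()) if n else np.nan,
            "n_vines": n,
            "t_statistic": np.nan,
            "p_value": np.nan,
            "reason": "",
        }
        if n < 3:
            row["reason"] = "too_few_vines"
        elif np.ptp(vals) == 0:
            row["reason"] = "zero_variance"
        else:
            t, p = stats.ttest_1samp(vals, popmean=0.0)
            row["t_statistic"], row["p_value"] = float(t), float(p)
        rows.append(row)
    out = pd.DataFrame(rows)
    if adjust:
        tested = out["p_value"].notna()
        q = np.full(len(out), np.nan)
        if tested.any():
            q[tested.to_numpy()] = bh_adjust(out.loc[tested, "p_value"].to_numpy())
        out["q_value"] = q
    return out


def first_tendril_node(dataset: LeafDataset) -> pd.Series:
    """Per vine, the smallest Ln whose opposite organ is a tendril.

    Vines without any tendril are absent from the result. Nodes coded N
    (no organ) are simply non-tendril; unknown codes are excluded from the
    scan with a warning.
    """
    result = {}
    warned = False
    for vine_id, recs in dataset.by_vine().items():
        nodes = []
        for r in recs:
            if r.organ_opposite == "unknown":
                if not warned:
                    warnings.warn(
                        "leaves with unknown organ codes are excluded from the "
                        "first-tendril-node scan",
                        stacklevel=2,
                    )
                    warned = True
                continue
            if r.organ_opposite == "T":
                nodes.append(r.leaf_number)
        if nodes:
            result[vine_id] = min(nodes)
    return pd.Series(result, dtype=int, name="first_tendril_node")


def tendril_correlation(per_vine_relative, per_vine_tendril) -> tuple[float, float, int]:
    """Spearman's rho between per-vine mean relative values and first
    tendril node, over vines carrying both. Returns (rho, p, n_vines)."""
    rel = pd.Series(per_vine_relative, dtype=float)
    ten = pd.Series(per_vine_tendril, dtype=float)
    both = rel.index.intersection(ten.index)
    x = rel.loc[both].to_numpy()
    y = ten.loc[both].to_numpy()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValidationError(
            f"tendril correlation requires >= 4 complete vine pairs, got {len(x)}"
        )
    rho, p = spearman(x, y)
    return rho, p, len(x)


@dataclass
class HeterochronyReport:
    """Per-leaf, per-vine and per-species heterochrony tables."""

    target_kind: str
    per_leaf: pd.DataFrame  # leaf_id, vine_id, species, actual, apparent, relative
    per_vine: pd.DataFrame  # vine_id, species, mean_relative, n_leaves
    per_species: pd.DataFrame  # species, mean_of_vine_means, t, p, n_vines, reason
    tendril: tuple[float, float, int] | None = None  # (rho, p, n_vines)


def build_report(
    dataset: LeafDataset,
    predictions: pd.DataFrame,
    target_kind: str = "leaf_number",
    adjust: bool = False,
) -> HeterochronyReport:
    """Assemble the full heterochrony report from staged leaves.

    ``predictions`` needs leaf_id, actual, apparent columns (e.g. the
    output of :func:`~latentleaf.discriminant.cross_stage`). The tendril
    correlation is computed when the dataset carries organ codes and at
    least 4 vines have both a tendril and staged leaves; otherwise it is
    absent.
    """
    meta = dataset.metadata_frame().set_index("leaf_id")
    pred = predictions.set_index("leaf_id")
    missing = pred.index.difference(meta.index)
    if len(missing):
        raise ValidationError(f"predictions reference unknown leaves: {list(missing[:3])}")
    per_leaf = pd.DataFrame(
        {
            "leaf_id": pred.index,
            "vine_id": meta.loc[pred.index, "vine_id"].to_numpy(),
            "species": meta.loc[pred.index, "species"].to_numpy(),
            "actual": pred["actual"].to_numpy(dtype=int),
            "apparent": pred["apparent"].to_numpy(dtype=int),
        }
    )
    per_leaf["relative"] = relative_values(per_leaf["actual"], per_leaf["apparent"])

    pv = vine_means(per_leaf["relative"], per_leaf["vine_id"])
    vine_species = per_leaf.drop_duplicates("vine_id").set_index("vine_id")["species"]
    pv.insert(1, "species", vine_species.loc[pv["vine_id"]].to_numpy())
    ps = species_offsets(pv, adjust=adjust)

    tendril = None
    tn = first_tendril_node(dataset)
    if len(tn):
        rel = pv.set_index("vine_id")["mean_relative"]
        try:
            tendril = tendril_correlation(rel, tn)
        except ValidationError:
            tendril = None
    return HeterochronyReport(
        target_kind=target_kind,
        per_leaf=per_leaf,
        per_vine=pv,
        per_species=ps,
        tendril=tendril,
    )
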