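"""Domain types and I/O for 17-landmark grapevine leaf datasets.

A leaf is recorded as 17 ordered planar landmarks placed on homologous
features of the blade (petiolar junction, midvein tip, sinuses, lobe tips,
vein termini and branch points), plus shoot metadata: the vine (genetic
accession) it came from, its species, its developmental stage ``Sn``
(counted from the shoot tip, S1 = youngest measurable leaf) and its leaf
number ``Ln`` (counted from the shoot base, L1 = first leaf), and the organ
opposite its node (C = cluster, T = tendril, N = no organ).

Because Sn and Ln count the same nodes from opposite ends of one shoot,
within a vine ``Sn + Ln`` is constant and equals total leaves + 1; this is
enforced at read time (with a lenient mode for field collections where the
smallest tip leaves could not be flattened and scanned).

Coordinates are accepted in image convention (y may increase downward); no
axis flip is applied on read, because downstream superimposition with
reflection allowed makes the orientation immaterial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, InitVar
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

N_LANDMARKS = 17

#: Fixed landmark identities, by position (1-based in file formats).
LANDMARK_NAMES = (
    "petiolar junction",
    "midvein tip",
    "left distal sinus",
    "right distal sinus",
    "left distal lobe tip",
    "right distal lobe tip",
    "left proximal sinus",
    "right proximal sinus",
    "left proximal lobe tip",
    "right proximal lobe tip",
    "left terminus petiolar vein",
    "right terminus petiolar vein",
    "branch point midvein",
    "branch point left distal vein",
    "branch point right distal vein",
    "branch point left proximal vein",
    "branch point right proximal vein",
)

ORGAN_CODES = ("C", "T", "N", "unknown")

METADATA_COLUMNS = ["leaf_id", "vine_id", "species", "stage", "leaf_number", "organ_opposite"]
WIDE_COORD_COLUMNS = [f"{a}{i}" for i in range(1, N_LANDMARKS + 1) for a in ("x", "y")]


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One leaf's 17 ordered (x, y) landmarks in arbitrary planar units."""

    coords: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (N_LANDMARKS, 2):
            raise ValidationError(
                f"a configuration requires exactly {N_LANDMARKS} landmarks "
                f"(17 landmarks, 2 coordinates each); got array of shape {c.shape}"
            )
        if not np.all(np.isfinite(c)):
            raise ValidationError("landmark coordinates must all be finite")
        if np.allclose(c, c[0], atol=0.0):
            raise ValidationError(
                "degenerate configuration: all landmarks coincide (centroid size 0)"
            )
        c.setflags(write=False)
        object.__setattr__(self, "coords", c)

    def __eq__(self, other):
        if not isinstance(other, LandmarkConfiguration):
            return NotImplemented
        return np.array_equal(self.coords, other.coords)

    def __hash__(self):
        return hash(self.coords.tobytes())


@dataclass(frozen=True)
class LeafRecord:
    """A landmarked leaf plus its shoot context."""

    leaf_id: str
    vine_id: str
    species: str
    stage: int
    leaf_number: int
    organ_opposite: str
    config: LandmarkConfiguration

    def __post_init__(self):
        for name in ("stage", "leaf_number"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and not isinstance(v, bool)) or v < 1:
                raise ValidationError(
                    f"leaf {self.leaf_id!r}: {name} must be a positive integer, got {v!r}"
                )
            object.__setattr__(self, name, int(v))
        if self.organ_opposite not in ORGAN_CODES:
            raise ValidationError(
                f"leaf {self.leaf_id!r}: organ_opposite must be one of {ORGAN_CODES}, "
                f"got {self.organ_opposite!r}"
            )

    @property
    def total_leaves(self) -> int:
        """Shoot total implied by this leaf: Sn + Ln − 1."""
        return self.stage + self.leaf_number - 1


@dataclass
class LeafDataset:
    """A validated collection of :class:`LeafRecord`.

    ``strict=False`` downgrades the per-vine Sn/Ln consistency rules to
    warnings; leaf_id uniqueness is always enforced.
    """

    records: list[LeafRecord] = field(default_factory=list)
    provenance: str = ""
    strict: InitVar[bool] = True

    def __post_init__(self, strict: bool):
        self.records = list(self.records)
        self.validate(strict=strict)

    # -- validation ------------------------------------------------------

    def validate(self, strict: bool = True) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.leaf_id in seen:
                raise ValidationError(f"duplicate leaf_id {r.leaf_id!r}")
            seen.add(r.leaf_id)
        for vine_id, recs in self.by_vine().items():
            self._check_vine(vine_id, recs, strict)

    @staticmethod
    def _check_vine(vine_id: str, recs: Sequence[LeafRecord], strict: bool) -> None:
        def fail(msg: str) -> None:
            if strict:
                raise ValidationError(msg)
            warnings.warn(msg, stacklevel=4)

        stages = [r.stage for r in recs]
        lns = [r.leaf_number for r in recs]
        if len(set(stages)) != len(stages):
            fail(f"vine {vine_id!r}: duplicate stage (Sn) values")
        if len(set(lns)) != len(lns):
            fail(f"vine {vine_id!r}: duplicate leaf_number (Ln) values")
        totals = {r.total_leaves for r in recs}
        if len(totals) > 1:
            fail(
                f"vine {vine_id!r}: Sn + Ln is not constant across leaves "
                f"(implied totals {sorted(totals)})"
            )

    # -- container protocol ---------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[LeafRecord]:
        return iter(self.records)

    def __eq__(self, other):
        if not isinstance(other, LeafDataset):
            return NotImplemented
        return self.records == other.records and self.provenance == other.provenance

    # -- accessors -------------------------------------------------------

    def by_vine(self) -> dict[str, list[LeafRecord]]:
        out: dict[str, list[LeafRecord]] = {}
        for r in self.records:
            out.setdefault(r.vine_id, []).append(r)
        return out

    def leaf_ids(self) -> list[str]:
        return [r.leaf_id for r in self.records]

    def coords_array(self) -> np.ndarray:
        """All configurations stacked as an (n, 17, 2) array."""
        if not self.records:
            return np.empty((0, N_LANDMARKS, 2))
        return np.stack([r.config.coords for r in self.records])

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "leaf_id": [r.leaf_id for r in self.records],
                "vine_id": [r.vine_id for r in self.records],
                "species": [r.species for r in self.records],
                "stage": [r.stage for r in self.records],
                "leaf_number": [r.leaf_number for r in self.records],
                "organ_opposite": [r.organ_opposite for r in self.records],
            }
        )

    def subset(self, keep: Iterable[str]) -> "LeafDataset":
        keep = set(keep)
        return LeafDataset(
            [r for r in self.records if r.leaf_id in keep],
            provenance=self.provenance,
            strict=False,
        )


# ---------------------------------------------------------------------------
# reading and writing
# ---------------------------------------------------------------------------

def _records_from_frame(meta: pd.DataFrame, coords: np.ndarray, source: str) -> list[LeafRecord]:
    records = []
    for i, row in enumerate(meta.itertuples(index=False)):
        try:
            records.append(
                LeafRecord(
                    leaf_id=str(row.leaf_id),
                    vine_id=str(row.vine_id),
                    species=str(row.species),
                    stage=_as_positive_int(row.stage, "stage", row.leaf_id),
                    leaf_number=_as_positive_int(row.leaf_number, "leaf_number", row.leaf_id),
                    organ_opposite=str(row.organ_opposite),
                    config=LandmarkConfiguration(coords[i]),
                )
            )
        except ValidationError as e:
            raise ValidationError(f"{source}: {e}") from e
    return records


def _as_positive_int(v, name: str, leaf_id) -> int:
    try:
        f = float(v)
    except (TypeError, ValueError):
        raise ValidationError(f"leaf {leaf_id!r}: {name} must be a positive integer, got {v!r}")
    if not np.isfinite(f) or f != int(f):
        raise ValidationError(f"leaf {leaf_id!r}: {name} must be a positive integer, got {v!r}")
    return int(f)


def _prepare_meta(df: pd.DataFrame, path: str) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in df.columns and c != "organ_opposite"]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    meta = df.copy()
    if "organ_opposite" not in meta.columns:
        meta["organ_opposite"] = "unknown"
    meta["organ_opposite"] = meta["organ_opposite"].fillna("unknown")
    return meta


def read_landmark_table(
    path,
    dialect: str = "wide_csv",
    strict: bool = True,
    sidecar=None,
    provenance: str | None = None,
) -> LeafDataset:
    """Read a landmark table into a validated :class:`LeafDataset`.

    Dialects
    --------
    ``wide_csv``
        header ``leaf_id,vine_id,species,stage,leaf_number,organ_opposite,
        x1,y1,...,x17,y17`` (canonical; ``organ_opposite`` optional).
    ``long_csv``
        one landmark per row: ``...,landmark,x,y`` with landmark in 1..17.
    ``tps``
        standard ``LM=17`` blocks keyed by ``ID=``; shoot metadata comes
        from a ``sidecar`` CSV with the wide metadata columns, keyed by
        leaf_id. Read-only.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    if dialect == "wide_csv":
        meta, coords = _read_wide(path)
    elif dialect == "long_csv":
        meta, coords = _read_long(path)
    elif dialect == "tps":
        meta, coords = _read_tps(path, sidecar)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    records = _records_from_frame(meta, coords, str(path))
    return LeafDataset(
        records,
        provenance=provenance if provenance is not None else f"{path.name} ({dialect})",
        strict=strict,
    )


def _read_wide(path: Path):
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as e:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {e}") from e
    missing_coords = [c for c in WIDE_COORD_COLUMNS if c not in df.columns]
    if missing_coords:
        raise ValidationError(
            f"{path}: expected 17 landmarks ({len(WIDE_COORD_COLUMNS)} coordinate "
            f"columns); missing {missing_coords[:4]}{'...' if len(missing_coords) > 4 else ''}"
        )
    meta = _prepare_meta(df, str(path))
    coords_flat = df[WIDE_COORD_COLUMNS].to_numpy(dtype=float)
    bad = ~np.isfinite(coords_flat).all(axis=1)
    if bad.any():
        leaf = df.loc[np.flatnonzero(bad)[0], "leaf_id"]
        raise ValidationError(
            f"{path}: leaf {leaf!r} does not provide 17 landmarks "
            "(missing or non-numeric coordinates)"
        )
    return meta, coords_flat.reshape(-1, N_LANDMARKS, 2)


def _read_long(path: Path):
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as e:  # pragma: no cover
        raise ParseError(f"{path}: {e}") from e
    for c in ("landmark", "x", "y"):
        if c not in df.columns:
            raise ParseError(f"{path}: long dialect requires column {c!r}")
    meta_rows, coord_rows = [], []
    for leaf_id, grp in df.groupby("leaf_id", sort=False):
        lms = grp["landmark"].to_numpy()
        if len(grp) != N_LANDMARKS or sorted(lms) != list(range(1, N_LANDMARKS + 1)):
            raise ValidationError(
                f"{path}: leaf {leaf_id!r} must provide exactly 17 landmarks "
                f"numbered 1..17; got {len(grp)} rows"
            )
        grp = grp.sort_values("landmark")
        meta_rows.append(grp.iloc[0])
        coord_rows.append(grp[["x", "y"]].to_numpy(dtype=float))
    if not meta_rows:
        return _prepare_meta(df.iloc[0:0], str(path)), np.empty((0, N_LANDMARKS, 2))
    meta = _prepare_meta(pd.DataFrame(meta_rows).reset_index(drop=True), str(path))
    return meta, np.stack(coord_rows)


def _read_tps(path: Path, sidecar):
    if sidecar is None:
        raise ParseError(f"{path}: the tps dialect requires a metadata sidecar CSV")
    blocks: list[tuple[str, np.ndarray]] = []
    lm_expected = pts = None
    cur: list[list[float]] = []
    cur_id = None
    scale = 1.0

    def flush(lineno):
        nonlocal cur, cur_id, scale, lm_expected
        if lm_expected is None:
            return
        if len(cur) != lm_expected:
            raise ParseError(
                f"{path}: line {lineno}: block has {len(cur)} points, LM={lm_expected}"
            )
        if lm_expected != N_LANDMARKS:
            raise ValidationError(
                f"{path}: block {cur_id!r} declares LM={lm_expected}; 17 landmarks required"
            )
        if cur_id is None:
            raise ParseError(f"{path}: line {lineno}: block without ID= key")
        blocks.append((cur_id, np.asarray(cur, dtype=float) * scale))
        cur, cur_id, scale, lm_expected = [], None, 1.0, None

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            if key.upper() == "LM":
                flush(lineno)
                try:
                    lm_expected = int(val)
                except ValueError:
                    raise ParseError(f"{path}: line {lineno}: bad LM= value {val!r}")
            elif key.upper() == "ID":
                cur_id = val.strip()
            elif key.upper() in ("IMAGE", "COMMENT"):
                continue
            elif key.upper() == "SCALE":
                scale = float(val)
            else:
                parts = line.split()
                if len(parts) != 2:
                    raise ParseError(f"{path}: line {lineno}: expected 'x y', got {line!r}")
                try:
                    cur.append([float(parts[0]), float(parts[1])])
                except ValueError:
                    raise ParseError(f"{path}: line {lineno}: non-numeric coordinate")
        flush("<eof>")

    side = pd.read_csv(sidecar)
    side = _prepare_meta(side, str(sidecar)).set_index(side["leaf_id"].astype(str))
    meta_rows, coords = [], []
    for leaf_id, arr in blocks:
        if leaf_id not in side.index:
            raise ValidationError(f"{path}: leaf {leaf_id!r} has no row in sidecar {sidecar}")
        meta_rows.append(side.loc[leaf_id])
        coords.append(arr)
    meta = pd.DataFrame(meta_rows).reset_index(drop=True)
    return meta, np.stack(coords) if coords else np.empty((0, N_LANDMARKS, 2))


def write_landmark_table(dataset: LeafDataset, path, dialect: str = "wide_csv") -> None:
    """Write a dataset so that :func:`read_landmark_table` recovers it exactly.

    Coordinates are written with 17 significant digits (binary-exact
    roundtrip for doubles). TPS is read-only convenience and not supported
    here.
    """
    path = Path(path)
    meta = dataset.metadata_frame()
    coords = dataset.coords_array()
    if dialect == "wide_csv":
        if len(dataset) == 0:
            pd.DataFrame(columns=METADATA_COLUMNS + WIDE_COORD_COLUMNS).to_csv(path, index=False)
            return
        flat = coords.reshape(len(dataset), -1)
        df = pd.concat(
            [meta, pd.DataFrame(flat, columns=WIDE_COORD_COLUMNS, index=meta.index)], axis=1
        )
        df.to_csv(path, index=False)
    elif dialect == "long_csv":
        if len(dataset) == 0:
            cols = METADATA_COLUMNS + ["landmark", "x", "y"]
            pd.DataFrame(columns=cols).to_csv(path, index=False)
            return
        rep = meta.loc[meta.index.repeat(N_LANDMARKS)].reset_index(drop=True)
        rep["landmark"] = np.tile(np.arange(1, N_LANDMARKS + 1), len(dataset))
        rep["x"] = coords[:, :, 0].ravel()
        rep["y"] = coords[:, :, 1].ravel()
        rep.to_csv(path, index=False)
    else:
        raise ValueError(f"cannot write dialect {dialect!r}")


# ---------------------------------------------------------------------------
# subsetting and summaries
# ---------------------------------------------------------------------------

def select_positions(
    dataset: LeafDataset,
    mode: str,
    lo: int | None = None,
    hi: int | None = None,
    n_mid: int = 4,
) -> LeafDataset:
    """Restrict a dataset to the shoot positions used by an analysis.

    ``stage_window`` keeps leaves with lo ≤ Sn ≤ hi; ``leafnum_window``
    keeps lo ≤ Ln ≤ hi; ``midshoot`` keeps, per vine, the ``n_mid`` leaves
    whose Ln is closest to the shoot midpoint (total + 1)/2, ties broken
    toward the shoot base (lower Ln). Idempotent; may return an empty
    dataset.
    """
    if mode in ("stage_window", "leafnum_window"):
        if lo is None or hi is None:
            raise ValueError(f"mode {mode!r} requires lo and hi")
        if lo > hi:
            raise ValueError(f"lo must be <= hi, got ({lo}, {hi})")
        attr = "stage" if mode == "stage_window" else "leaf_number"
        keep = [r.leaf_id for r in dataset if lo <= getattr(r, attr) <= hi]
    elif mode == "midshoot":
        if n_mid < 1:
            raise ValueError("n_mid must be >= 1")
        keep = []
        for recs in dataset.by_vine().values():
            total = recs[0].total_leaves
            mid = (total + 1) / 2
            ranked = sorted(recs, key=lambda r: (abs(r.leaf_number - mid), r.leaf_number))
            keep.extend(r.leaf_id for r in ranked[:n_mid])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return dataset.subset(keep)


@dataclass
class DatasetSummary:
    """Count tables mirroring a collection overview figure."""

    species: pd.DataFrame  # index species; columns n_vines, n_leaves
    by_stage: pd.Series  # index Sn; leaf counts
    by_leaf_number: pd.Series  # index Ln; leaf counts
    organs: pd.Series  # index organ code; leaf counts


def summarize(dataset: LeafDataset) -> DatasetSummary:
    """Per-species vine and leaf counts, per-Sn/Ln counts, organ counts."""
    meta = dataset.metadata_frame()
    if meta.empty:
        return DatasetSummary(
            species=pd.DataFrame(columns=["n_vines", "n_leaves"]),
            by_stage=pd.Series(dtype=int, name="n_leaves"),
            by_leaf_number=pd.Series(dtype=int, name="n_leaves"),
            organs=pd.Series(dtype=int, name="n_leaves"),
        )
    species = meta.groupby("species").agg(
        n_vines=("vine_id", "nunique"), n_leaves=("leaf_id", "count")
    )
    return DatasetSummary(
        species=species,
        by_stage=meta.groupby("stage")["leaf_id"].count().rename("n_leaves"),
        by_leaf_number=meta.groupby("leaf_number")["leaf_id"].count().rename("n_leaves"),
        organs=meta.groupby("organ_opposite")["leaf_id"].count().rename("n_leaves"),
    )
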