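"""Synthetic grapevine shoots with known latent-shape ground truth.

Each simulated vine is one shoot: a series of nodes counted as leaf number
Ln from the base and developmental stage Sn from the tip (so Sn + Ln =
total leaves + 1 at every node). A leaf's noiseless shape is the sum, in
the 34-dimensional flattened landmark space, of

* a grape-like 17-landmark template (unit centroid size),
* a species effect A_s (a fixed displacement per species),
* an ontogenetic effect along a unit direction u, decaying with Sn as
  ``exp(−(Sn−1)/tau_S)`` — strongest in the youngest leaves at the tip,
* a heteroblastic effect along a unit direction w, saturating with the
  vine-shifted leaf number as ``1 − exp(−(L_eff−1)/tau_L)`` where
  ``L_eff = Ln + δ_v`` and δ_v is the vine's heterochronic shift in nodes.

u and w are constructed orthonormal and orthogonal to every A_s, so the
developmental and species subspaces are separable by construction (a
``confounded`` mode tilts w toward u to test robustness). Per-coordinate
Gaussian landmark noise is added, and each raw configuration is placed
arbitrarily in the plane (random rotation, translation, log-uniform scale,
reflection with probability ½) to emulate scanned leaves.

The organ series opposite the nodes follows the grapevine pattern: every
third node bears nothing (N); below the vine's tendril onset node the
remaining nodes bear flower clusters (C), at and above it tendrils (T).
The onset node is coupled to the heterochronic shift with slope −γ (a
precociously adult vine, δ_v > 0, tendrils earlier), plus unit node noise.

Shoot lengths are Poisson around ``mean_total_leaves`` (floored at 10 so
the S1–S10 and L1–L10 analysis windows are always populated); shoot-length
variability is exactly what decouples Sn from Ln across vines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .leafdata import LandmarkConfiguration, LeafDataset, LeafRecord

# Hard-coded grape-like 17-landmark outline (arbitrary units; normalized to
# unit centroid size below). Ordering follows the standard scheme: petiolar
# junction, midvein tip, distal sinuses/lobes, proximal sinuses/lobes,
# petiolar vein termini, then vein branch points.
_TEMPLATE_RAW = np.array(
    [
        [0.00, 0.00],  # 1  petiolar junction
        [0.00, 1.00],  # 2  midvein tip
        [-0.18, 0.62],  # 3  left distal sinus
        [0.18, 0.62],  # 4  right distal sinus
        [-0.55, 0.72],  # 5  left distal lobe tip
        [0.55, 0.72],  # 6  right distal lobe tip
        [-0.38, 0.25],  # 7  left proximal sinus
        [0.38, 0.25],  # 8  right proximal sinus
        [-0.75, 0.28],  # 9  left proximal lobe tip
        [0.75, 0.28],  # 10 right proximal lobe tip
        [-0.30, -0.12],  # 11 left terminus petiolar vein
        [0.30, -0.12],  # 12 right terminus petiolar vein
        [0.00, 0.35],  # 13 branch point midvein
        [-0.22, 0.42],  # 14 branch point left distal vein
        [0.22, 0.42],  # 15 branch point right distal vein
        [-0.12, 0.12],  # 16 branch point left proximal vein
        [0.12, 0.12],  # 17 branch point right proximal vein
    ]
)
_c = _TEMPLATE_RAW - _TEMPLATE_RAW.mean(axis=0)
DEFAULT_TEMPLATE = _c / np.sqrt((_c**2).sum())
DEFAULT_TEMPLATE.setflags(write=False)
del _c


@dataclass(frozen=True)
class TransformRanges:
    """Placement ranges for raw configurations."""

    rotation: tuple[float, float] = (0.0, 2.0 * np.pi)
    translation: tuple[float, float] = (-10.0, 10.0)
    log_scale: tuple[float, float] = (np.log(0.5), np.log(2.0))
    reflection: bool = True


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one simulated collection.

    All shape scales are in units of the (unit-centroid-size) template;
    tau_S/tau_L are trajectory decay constants in nodes; heterochrony_sd
    is the s.d. of the vine-level shift δ_v in nodes; ``fixed_shoot_length``
    makes every shoot exactly round(mean_total_leaves) nodes long, so Sn
    and Ln are perfectly anti-indexed across vines; ``species_shift``
    optionally adds a fixed per-species offset to δ_v (for injected-shift
    recovery studies); ``tendril_coupling`` γ moves the tendril onset node
    by −γ nodes per node of δ_v. ``effect_seed`` fixes the latent
    directions and species effects separately from the sampling seed, so
    matched collections can share one generative model (defaults to
    ``seed``). ``seed`` fixes the entire output bit-for-bit.
    """

    n_species: int = 3
    vines_per_species: int = 10
    mean_total_leaves: float = 25.0
    fixed_shoot_length: bool = False
    template: np.ndarray | None = None
    species_effect_scale: float = 0.15
    stage_effect_scale: float = 0.25
    leafnum_effect_scale: float = 0.25
    tau_S: float = 3.0
    tau_L: float = 3.0
    heterochrony_sd: float = 1.0
    species_shift: tuple[float, ...] | None = None
    tendril_base: int = 5
    tendril_coupling: float = 1.0
    noise_sd: float = 0.01
    transforms: TransformRanges | None = field(default_factory=TransformRanges)
    confounded_cos: float = 0.0  # cos(u, w) > 0 breaks the separability assumption
    seed: int = 0
    effect_seed: int | None = None

    def __post_init__(self):
        if self.n_species < 1 or self.vines_per_species < 1:
            raise ValidationError("n_species and vines_per_species must be >= 1")
        if self.mean_total_leaves < 10:
            raise ValidationError("mean_total_leaves must be >= 10 so S1-S10/L1-L10 are populated")
        for name in (
            "species_effect_scale",
            "stage_effect_scale",
            "leafnum_effect_scale",
            "heterochrony_sd",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.tau_S <= 0 or self.tau_L <= 0:
            raise ValidationError("tau_S and tau_L must be > 0")
        if self.species_shift is not None and len(self.species_shift) != self.n_species:
            raise ValidationError("species_shift must give one value per species")
        if not -1.0 < self.confounded_cos < 1.0:
            raise ValidationError("confounded_cos must lie in (-1, 1)")
        if self.tendril_base < 1:
            raise ValidationError("tendril_base must be >= 1")


@dataclass
class SyntheticTruth:
    """Everything needed to check parameter recovery downstream."""

    species: list[str]
    species_effects: dict[str, np.ndarray]  # flattened 34-vectors
    u: np.ndarray  # stage direction, unit 34-vector
    w: np.ndarray  # leaf-number direction, unit 34-vector
    delta: dict[str, float]  # per-vine heterochronic shift (nodes)
    total_leaves: dict[str, int]
    tendril_onset: dict[str, int]  # the generative onset node t_v
    first_tendril_node: dict[str, int]  # first node actually bearing a T
    noiseless: dict[str, np.ndarray]  # per-leaf pre-noise (17, 2) shapes

    def to_json(self, path) -> None:
        doc = {
            "species": self.species,
            "species_effects": {k: v.tolist() for k, v in self.species_effects.items()},
            "u": self.u.tolist(),
            "w": self.w.tolist(),
            "delta": self.delta,
            "total_leaves": self.total_leaves,
            "tendril_onset": self.tendril_onset,
            "first_tendril_node": self.first_tendril_node,
        }
        Path(path).write_text(json.dumps(doc))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _latent_model(config: SyntheticConfig):
    """Draw u, w and the species effects from the effect seed."""
    rng = np.random.default_rng(config.seed if config.effect_seed is None else config.effect_seed)
    d = 34
    u = _unit(rng.standard_normal(d))
    w_raw = rng.standard_normal(d)
    w = _unit(w_raw - (w_raw @ u) * u)
    if config.confounded_cos != 0.0:
        c = config.confounded_cos
        w = _unit(c * u + np.sqrt(1 - c**2) * w)
    effects = {}
    names = [f"species_{i + 1:02d}" for i in range(config.n_species)]
    for name in names:
        a = rng.standard_normal(d)
        a -= (a @ u) * u
        a -= (a @ w) * w
        effects[name] = _unit(a) * config.species_effect_scale
    return names, u, w, effects


def generate(config: SyntheticConfig) -> tuple[LeafDataset, SyntheticTruth]:
    """Simulate a collection of shoots; returns (dataset, ground truth)."""
    template = DEFAULT_TEMPLATE if config.template is None else np.asarray(config.template, float)
    if template.shape != (17, 2):
        raise ValidationError("template must be a 17x2 landmark array")
    t_flat = template.reshape(-1)

    names, u, w, effects = _latent_model(config)
    rng = np.random.default_rng(config.seed)

    records: list[LeafRecord] = []
    delta: dict[str, float] = {}
    totals: dict[str, int] = {}
    onset: dict[str, int] = {}
    first_t: dict[str, int] = {}
    noiseless: dict[str, np.ndarray] = {}

    for si, sp in enumerate(names):
        shift = 0.0 if config.species_shift is None else float(config.species_shift[si])
        for vi in range(config.vines_per_species):
            vine_id = f"{sp}_v{vi + 1:02d}"
            if config.fixed_shoot_length:
                T_v = max(10, int(round(config.mean_total_leaves)))
            else:
                T_v = max(10, int(rng.poisson(config.mean_total_leaves)))
            d_v = float(rng.normal(0.0, config.heterochrony_sd)) + shift
            t_v = int(np.clip(
                np.round(config.tendril_base - config.tendril_coupling * d_v + rng.normal(0, 1)),
                1,
                T_v,
            ))
            delta[vine_id] = d_v
            totals[vine_id] = T_v
            onset[vine_id] = t_v

            for ln in range(1, T_v + 1):
                sn = T_v + 1 - ln
                leaf_id = f"{vine_id}_L{ln:02d}"
                shape = (
                    t_flat
                    + effects[sp]
                    + config.stage_effect_scale * np.exp(-(sn - 1) / config.tau_S) * u
                    + config.leafnum_effect_scale
                    * (1.0 - np.exp(-(ln + d_v - 1) / config.tau_L))
                    * w
                )
                clean = shape.reshape(17, 2)
                noiseless[leaf_id] = clean
                coords = clean + rng.normal(0.0, config.noise_sd, size=(17, 2))
                if config.transforms is not None:
                    coords = _place(coords, config.transforms, rng)

                if ln % 3 == 0:
                    organ = "N"
                elif ln < t_v:
                    organ = "C"
                else:
                    organ = "T"
                if organ == "T" and vine_id not in first_t:
                    first_t[vine_id] = ln
                records.append(
                    LeafRecord(
                        leaf_id=leaf_id,
                        vine_id=vine_id,
                        species=sp,
                        stage=sn,
                        leaf_number=ln,
                        organ_opposite=organ,
                        config=LandmarkConfiguration(coords),
                    )
                )

    dataset = LeafDataset(records, provenance=f"synthetic seed={config.seed}")
    truth = SyntheticTruth(
        species=names,
        species_effects=effects,
        u=u,
        w=w,
        delta=delta,
        total_leaves=totals,
        tendril_onset=onset,
        first_tendril_node=first_t,
        noiseless=noiseless,
    )
    return dataset, truth


def _place(coords: np.ndarray, tr: TransformRanges, rng: np.random.Generator) -> np.ndarray:
    theta = rng.uniform(*tr.rotation)
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    s = float(np.exp(rng.uniform(*tr.log_scale)))
    t = rng.uniform(*tr.translation, size=2)
    out = coords @ R.T * s
    if tr.reflection and rng.random() < 0.5:
        out = out * np.array([-1.0, 1.0])
    return out + t


def truth_summary(truth: SyntheticTruth) -> pd.DataFrame:
    """Per-vine ground-truth table for recovery checks."""
    vines = sorted(truth.delta)
    sp = {v: "_".join(v.split("_")[:-1]) for v in vines}
    return pd.DataFrame(
        {
            "vine_id": vines,
            "species": [sp[v] for v in vines],
            "delta": [truth.delta[v] for v in vines],
            "total_leaves": [truth.total_leaves[v] for v in vines],
            "tendril_onset": [truth.tendril_onset[v] for v in vines],
            "first_tendril_node": [truth.first_tendril_node.get(v) for v in vines],
            "species_effect_norm": [
                float(np.linalg.norm(truth.species_effects[sp[v]])) for v in vines
            ],
        }
    )


def node_effect_step(config: SyntheticConfig, window: tuple[int, int] = (1, 10)) -> float:
    """Mean adjacent-node heteroblastic shape displacement inside a window.

    The natural scale for landmark noise in node-resolution analyses: the
    average distance in shape space between consecutive leaf numbers.
    """
    lo, hi = window
    ln = np.arange(lo, hi + 1, dtype=float)
    pos = config.leafnum_effect_scale * (1.0 - np.exp(-(ln - 1) / config.tau_L))
    return float(np.abs(np.diff(pos)).mean())


def make_matched_pair(
    base: SyntheticConfig, test_shift: float, test_seed: int
) -> tuple[SyntheticConfig, SyntheticConfig]:
    """A train/test config pair sharing one latent model.

    The training collection is the base config with no heterochronic
    variation; the test collection injects a fixed shift of ``test_shift``
    nodes in every vine.
    """
    eff = base.seed if base.effect_seed is None else base.effect_seed
    train = replace(base, heterochrony_sd=0.0, species_shift=None, effect_seed=eff)
    test = replace(
        base,
        heterochrony_sd=0.0,
        species_shift=tuple([test_shift] * base.n_species),
        seed=test_seed,
        effect_seed=eff,
    )
    return train, test
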