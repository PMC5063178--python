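import numpy as np
import pytest

from latentleaf import (
    LandmarkConfiguration,
    LeafDataset,
    LeafRecord,
    SyntheticConfig,
    generate,
    gpa,
)


def random_config(rng: np.random.Generator, k: int = 17) -> np.ndarray:
    return rng.normal(size=(k, 2))


def make_record(
    leaf_id: str,
    vine_id: str = "v1",
    species: str = "sp1",
    stage: int = 1,
    leaf_number: int = 1,
    organ: str = "unknown",
    coords=None,
    rng=None,
) -> LeafRecord:
    if coords is None:
        rng = rng or np.random.default_rng(abs(hash(leaf_id)) % 2**31)
        coords = random_config(rng)
    return LeafRecord(
        leaf_id=leaf_id,
        vine_id=vine_id,
        species=species,
        stage=stage,
        leaf_number=leaf_number,
        organ_opposite=organ,
        config=LandmarkConfiguration(coords),
    )


def make_vine(vine_id: str, species: str, total: int, organs=None, rng=None) -> list[LeafRecord]:
    """A consistent vine of `total` leaves (Sn + Ln = total + 1)."""
    rng = rng or np.random.default_rng(0)
    organs = organs or ["unknown"] * total
    return [
        make_record(
            f"{vine_id}_L{ln}",
            vine_id=vine_id,
            species=species,
            stage=total + 1 - ln,
            leaf_number=ln,
            organ=organs[ln - 1],
            coords=random_config(rng),
        )
        for ln in range(1, total + 1)
    ]


@pytest.fixture
def tiny_dataset() -> LeafDataset:
    return LeafDataset(make_vine("v1", "sp1", 5) + make_vine("v2", "sp2", 7))


@pytest.fixture(scope="session")
def small_synth():
    config = SyntheticConfig(seed=7, n_species=2, vines_per_species=3, mean_total_leaves=12.0)
    return generate(config)


@pytest.fixture(scope="session")
def small_aligned(small_synth):
    dataset, _ = small_synth
    return gpa(dataset)
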