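import numpy as np
import pytest

import dietkit as dk
from dietkit.data import PreyCategory, StomachRecord


def make_record(fish_id, counts, weights=None, **meta):
    """Stomach record with weights defaulting to 0.1 g per item."""
    weights = weights if weights is not None else {k: 0.1 * v for k, v in counts.items()}
    for k in counts:
        weights.setdefault(k, 0.0)
    counts = {k: counts.get(k, 0.0) for k in weights}
    return StomachRecord(fish_id=fish_id, counts=counts, weights_g=weights, **meta)


@pytest.fixture
def lowest_taxonomy():
    return [
        PreyCategory("Tunicates", level="generalized"),
        PreyCategory("Euphausiids", level="generalized"),
        PreyCategory("Other", level="generalized"),
        PreyCategory("Salpidae", level="lowest", parent="Tunicates"),
        PreyCategory("Pyrosoma", level="lowest", parent="Tunicates"),
        PreyCategory("Euphausiacea", level="lowest", parent="Euphausiids"),
        PreyCategory("Polychaeta", level="lowest", parent="Other"),
    ]


@pytest.fixture
def tiny_dataset(lowest_taxonomy):
    """Five stomachs at the lowest taxonomic level, including an empty one."""
    recs = [
        make_record("f1", {"Salpidae": 3, "Pyrosoma": 2, "Euphausiacea": 0, "Polychaeta": 0}),
        make_record("f2", {"Salpidae": 0, "Pyrosoma": 0, "Euphausiacea": 2, "Polychaeta": 0},
                    weights={"Euphausiacea": 0.5}),
        make_record("f3", {"Salpidae": 1, "Pyrosoma": 0, "Euphausiacea": 1, "Polychaeta": 0}),
        make_record("f4", {"Salpidae": 0, "Pyrosoma": 0, "Euphausiacea": 0, "Polychaeta": 4}),
        make_record("f5", {"Salpidae": 0, "Pyrosoma": 0, "Euphausiacea": 0, "Polychaeta": 0}),
    ]
    return dk.DietDataset(records=recs, taxonomy=list(lowest_taxonomy))


@pytest.fixture(scope="session")
def study_config():
    return dk.scenario("study")


@pytest.fixture(scope="session")
def study_dataset(study_config):
    return dk.simulate_diet_dataset(study_config, seed=11)


@pytest.fixture(scope="session")
def analysis_dataset(study_dataset):
    """Study dataset after empty/Other exclusions: the input to every analysis stage."""
    return dk.apply_exclusions(study_dataset)


@pytest.fixture(scope="session")
def isotope_records(study_config):
    return dk.simulate_isotope_dataset(study_config, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
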