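import pytest

from orco_vscreen import LibrarySpec, generate_library, generate_training_set, train
from orco_vscreen.chem_io import MoleculeRecord, MoleculeSet, standardize


@pytest.fixture(scope="session")
def training_set():
    """Default synthetic training panel: 58 actives / 25 inactives."""
    return generate_training_set(LibrarySpec(seed=7))


@pytest.fixture(scope="session")
def potent_subset(training_set):
    """Actives with IC50 < 500 uM plus all inactives (potent-subset panel)."""
    keep = [r.id for r in training_set.actives if r.ic50_um < 500]
    keep += training_set.inactives.ids
    return training_set.subset(keep)


@pytest.fixture(scope="session")
def model_a(training_set):
    return train(training_set)


@pytest.fixture(scope="session")
def model_b(potent_subset):
    return train(potent_subset)


@pytest.fixture(scope="session")
def library_with_truth():
    """1280-compound synthetic library with 5% motif-bearing actives."""
    return generate_library(LibrarySpec(seed=7))


@pytest.fixture
def toy_set():
    """Two phenol actives vs two alkane inactives: trivially separable."""
    records = [
        MoleculeRecord("a1", "Oc1ccccc1C", label="active"),
        MoleculeRecord("a2", "Oc1ccccc1CC", label="active"),
        MoleculeRecord("i1", "CCCCCC", label="inactive"),
        MoleculeRecord("i2", "CCCCC", label="inactive"),
    ]
    return MoleculeSet([standardize(r) for r in records])
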