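import numpy as np
import pytest

from mdpost.store import BoxMetadata, ConfigurationBatch, SpeciesRecord, TrajectoryStore


@pytest.fixture
def nacl_box():
    return BoxMetadata((1e-9, 1e-9, 1e-9), timestep=1e-12, temperature=300.0)


@pytest.fixture
def nacl_species():
    return [
        SpeciesRecord("Na", (0, 1, 2, 3), mass=3.8e-26, charge_number=1),
        SpeciesRecord("Cl", (4, 5, 6, 7), mass=5.9e-26, charge_number=-1),
    ]


@pytest.fixture
def nacl_store(nacl_box, nacl_species):
    store = TrajectoryStore.create(None, nacl_box, nacl_species)
    yield store
    store.close()


def random_batch(rng, species, n_frames, properties=("positions",), scale=1e-9):
    data = {}
    for sp in species:
        props = {}
        for p in properties:
            if p == "image_flags":
                props[p] = rng.integers(-2, 3, size=(sp.count, n_frames, 3))
            else:
                props[p] = rng.uniform(0, scale, size=(sp.count, n_frames, 3))
        data[sp.name] = props
    return ConfigurationBatch(data)
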