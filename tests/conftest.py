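import numpy as np
import pytest

from morphoseq.morphometry import LandmarkConfiguration, ShapeDataset
from morphoseq.rules import default_rules
from morphoseq.synthetic_data import exemplar_set


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def exemplars(rules):
    return exemplar_set(rules)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_dataset(coords_by_group: dict[str, list[np.ndarray]]) -> ShapeDataset:
    configs = []
    for gname, shapes in coords_by_group.items():
        for i, X in enumerate(shapes):
            configs.append(
                LandmarkConfiguration(
                    specimen_id=f"{gname}_{i}", landmarks=np.asarray(X, float), group_label=gname
                )
            )
    return ShapeDataset(configurations=configs)


@pytest.fixture()
def triangle():
    return np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 1.0]])
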