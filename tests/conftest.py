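import numpy as np
import pytest

from hemafuse import CellClassSpec, generate_dataset, toy_backbone_config


def four_class_specs(count: int = 40) -> list[CellClassSpec]:
    """Well-separated 4-class synthetic design used across the suite."""
    return [
        CellClassSpec("classA", count, hue=0.0, nucleus_lobes=1),
        CellClassSpec("classB", count, hue=90.0, nucleus_lobes=2),
        CellClassSpec("classC", count, hue=180.0, nucleus_lobes=3),
        CellClassSpec("classD", count, hue=270.0, nucleus_lobes=1,
                      nucleus_fraction=0.6),
    ]


@pytest.fixture(scope="session")
def four_class_records():
    return generate_dataset(four_class_specs(), image_size_range=(64, 128),
                            seed=7)


@pytest.fixture(scope="session")
def toy_cfg():
    return toy_backbone_config()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
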