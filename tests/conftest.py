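import numpy as np
import pytest

from myoscreen.screen_analysis import LayoutEntry, PlateLayout


def make_layout(
    n_samples: int = 8,
    n_mock: int = 3,
    n_neg: int = 3,
    n_death: int = 0,
    replicates: int = 1,
    reagent_prefix: str = "reagent",
) -> PlateLayout:
    entries = {}
    for i in range(n_samples):
        for rep in range(1, replicates + 1):
            entries[f"S{i:03d}r{rep}"] = LayoutEntry(
                f"{reagent_prefix}{i:03d}", "sample", 100.0, rep
            )
    for j in range(n_mock):
        entries[f"M{j:02d}"] = LayoutEntry("mock", "mock")
    for j in range(n_neg):
        entries[f"N{j:02d}"] = LayoutEntry("neg_lna", "neg_ctrl")
    for j in range(n_death):
        entries[f"D{j:02d}"] = LayoutEntry("death_mix", "death_ctrl")
    return PlateLayout(entries=entries)


@pytest.fixture
def simple_layout() -> PlateLayout:
    return make_layout()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
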