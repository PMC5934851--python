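import numpy as np
import pytest

from gisniffer import CompositionModel, generate_background, plant_islands
from gisniffer.detector import DetectorParams


def random_dna(length, seed, gc=0.5):
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join("ACGT"[i] for i in rng.choice(4, size=length, p=p))


@pytest.fixture(scope="session")
def small_params():
    """Scan geometry scaled down for fast unit tests on ~100-kbp sequences."""
    return DetectorParams(
        ref_window=50_000, ref_step=20_000,
        local_window=5_000, local_step=1_000,
        min_island=3_000,
    )


@pytest.fixture(scope="session")
def background_120k():
    model = CompositionModel(gc=0.45, seed=11)
    return generate_background(120_000, model)


@pytest.fixture(scope="session")
def planted_truth():
    """1-Mbp chromosome with three GC-contrasted islands, default geometry."""
    model = CompositionModel(gc=0.45, seed=21)
    background = generate_background(1_000_000, model)
    specs = [
        (12_000, CompositionModel(gc=0.30, seed=121)),
        (30_000, CompositionModel(gc=0.55, seed=122)),
        (20_000, CompositionModel(gc=0.60, seed=123)),
    ]
    return plant_islands(background, specs, seed=21, background_model=model)
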