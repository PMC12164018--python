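import numpy as np
import pytest

from rcstpat import PhantomSpec, SensorGeometry, make_paired_dataset


@pytest.fixture(scope="session")
def geom64():
    """Scanner geometry scaled to a 64x64 grid (512 time samples)."""
    return SensorGeometry.for_grid(64, n_time=512)


@pytest.fixture(scope="session")
def paired_dataset_64(geom64):
    """20 vessel phantoms at 64x64, reconstructed at 32/64/128 projections.

    Session-scoped: the forward projections are the most expensive part of
    the suite and several experiments share them.
    """
    specs = [PhantomSpec(seed=s) for s in range(20)]
    return make_paired_dataset(specs, [32, 64, 128], geom64, size=64, seed=0)


def pairs_at_rate(pairs, rate):
    return [p for p in pairs if p.rate == rate]
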