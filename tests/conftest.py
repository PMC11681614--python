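import numpy as np
import pytest

from ssadhkin import (OrderedBiBiParams, PartialSubstrateInhibitionParams,
                      RateDataset, RateObservation)


@pytest.fixture
def bibi_params():
    return OrderedBiBiParams(vmax=100.0, k_a=10.0, k_b=1.0, k_ia=5.0)


@pytest.fixture
def partial_params():
    return PartialSubstrateInhibitionParams(
        vmax=100.0, k_a=10.0, k_b=1.0, k_ia=5.0, k_is=10.0, b=0.5)


def make_dataset(rate_fn, ssa_grid, nad_grid, **obs_kwargs):
    """Build a RateDataset by evaluating rate_fn(a, b) on a grid."""
    obs = []
    for s in ssa_grid:
        for a in nad_grid:
            obs.append(RateObservation(ssa_um=float(s), nad_um=float(a),
                                       rate=float(rate_fn(a, s)),
                                       **obs_kwargs))
    return RateDataset(obs)


@pytest.fixture
def make_grid_dataset():
    return make_dataset
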