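import numpy as np
import pytest

import microvasc as mv
from microvasc.synthesis import CorticalTargets


@pytest.fixture(scope="session")
def small_targets():
    """Reduced-extent sample (~0.36 mm^2) preserving all densities and
    calibres; used where only intensive properties matter."""
    return CorticalTargets(n_segments=6000)


@pytest.fixture(scope="session")
def small_sample(small_targets):
    return mv.synthesize_cortical_sample(small_targets, rng=11)


@pytest.fixture(scope="session")
def solved_small(small_sample):
    field = mv.solve_biphasic(small_sample)
    return small_sample, field


@pytest.fixture(scope="session")
def sample_ensemble():
    """Three full Table-1-scale cortical samples with converged biphasic
    solutions (the study conditions of the sample-scale analyses)."""
    out = []
    for seed in (101, 102, 103):
        net = mv.synthesize_cortical_sample(rng=seed)
        field = mv.solve_biphasic(net)
        out.append((net, field))
    return out


@pytest.fixture(scope="session")
def honeycomb():
    return mv.make_fixture("honeycomb_lattice", rows=3, cols=4)
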