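import numpy as np
import pytest

from mdstab import synthetic as syn
from mdstab.io_core import RegionSpec


@pytest.fixture(scope="session")
def chain_region():
    """All CA atoms of a 50-residue toy chain starting at author residue 339."""
    return RegionSpec("chain50", ((339, 388),))


@pytest.fixture(scope="session")
def two_state_traj(chain_region):
    """500-frame two-state Markov trajectory: templates 0.5 nm apart,
    jitter 0.01 nm, stationary populations 0.7/0.3, fixed seed."""
    model = syn.two_state_model(
        50, (0.7, 0.3), switch_rate=0.2, template_separation_nm=0.5,
        jitter_sd_nm=0.01,
    )
    return syn.gen_markov_trajectory(model, 500, seed=1)


@pytest.fixture(scope="session")
def complete_construct_atoms():
    """CA-only atom table spanning the full author numbering 339-725."""
    return syn.make_chain_atoms(725 - 339 + 1, first_residue=339)
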