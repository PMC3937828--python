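import numpy as np
import pytest

import fluxloops as fl
from fluxloops.loops import AnnealingSchedule


@pytest.fixture
def toy():
    """Four-reaction network with the internal two-cycle and v = (3,1,2,2)."""
    return fl.toy_network(0.0)


@pytest.fixture
def toy_sub(toy):
    net, v = toy
    return fl.build_thermo_subnetwork(net, v)


@pytest.fixture
def fast_schedule():
    """Annealing schedule sized for the few-reaction fixtures used in tests."""
    return AnnealingSchedule(n_stages=25, sweeps_per_stage=50, n_restarts=5,
                             seed=0)


def random_subnetwork(rng, n_metabolites=None, n_reactions=None):
    """Random signed subnetwork with integer coefficients in {-1, 0, 1}.

    Columns are guaranteed nonzero; the sign pattern is absorbed into the
    entries (equivalent to random flux directions over a random integer
    stoichiometry).
    """
    m = n_metabolites if n_metabolites is not None else int(rng.integers(2, 6))
    n = n_reactions if n_reactions is not None else int(rng.integers(2, 9))
    while True:
        om = rng.choice([-1, 0, 0, 1], size=(m, n)).astype(float)
        if (np.count_nonzero(om, axis=0) > 0).all():
            break
    return fl.ThermoSubnetwork(
        kept_reactions=np.arange(n),
        omega=om,
        direction_signs=np.ones(n, dtype=int),
        reaction_ids=[f"r{i}" for i in range(n)],
        n_reactions_total=n,
    )
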