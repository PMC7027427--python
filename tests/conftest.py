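"""Shared fixtures.

The expensive inputs — full-protocol signature simulations (N = 200,
t = 100) and the scaled-down regression library (N = 100, 5 runs per
parameter combination) — are session-scoped so the signature checks and the
accuracy regressions share one set of simulations.
"""

from __future__ import annotations

import numpy as np
import pytest

from swarmtopo import ModelParams, generate_library, simulate

#: One representative (C, ell) per signature phenotype.
SIGNATURE_COMBOS = {
    "double_ring": (0.1, 0.1),
    "single_mill": (0.5, 0.1),
    "double_mill": (0.9, 0.5),
    "escape_symmetric": (2.0, 0.9),
}


@pytest.fixture(scope="session")
def signature_runs():
    """Full-protocol simulations (N = 200, t = 100) of the four signature
    phenotypes, keyed by phenotype name."""
    return {
        name: simulate(ModelParams(C=c, ell=l), seed=7)
        for name, (c, l) in SIGNATURE_COMBOS.items()
    }


@pytest.fixture(scope="session")
def regression_library():
    """Scaled-down labeled library for the accuracy regressions: all 25
    (C, ell) combinations, 10 runs each, N = 50 agents — the protocol
    otherwise unchanged (t = 100, dt = 0.05, uniform initial conditions).
    N = 50 is the largest agent count at which the full benchmark completes
    at desk scale."""
    return generate_library(reps=10, base_seed=0, n_agents=50)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
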