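"""Shared fixtures.

The expensive full-model ensembles (300 repetitions each at the three
extrinsic-noise levels) are built once per session and shared between the
noise-analysis unit tests and the acceptance tests.
"""

import numpy as np
import pytest

from jakstat.engine import run_ensemble
from jakstat.model import (
    ParameterSet,
    Reaction,
    ReactionNetwork,
    SpeciesDef,
    SpeciesRole,
    COMPARTMENT_TABLE,
    build_canonical_model,
)
from jakstat.noise import InitialConditionSampler

HOURLY_GRID = np.linspace(0.0, 1920.0, 33)


def make_birth_death(k_b=5.0, k_d=1.0, x0=0.0) -> ReactionNetwork:
    """Birth-death process: 0 -> X at k_b, X -> 0 at k_d; stationary law
    Poisson(k_b/k_d)."""
    species = [SpeciesDef("X", "cytoplasm", SpeciesRole.PROTEIN, x0)]
    reactions = [
        Reaction("b", (), (("X", 1),), "k_b"),
        Reaction("d", (("X", 1),), (), "k_d"),
    ]
    params = ParameterSet({"k_b": k_b, "k_d": k_d}, {"k_b": "1/min", "k_d": "1/min"})
    return ReactionNetwork(species, COMPARTMENT_TABLE, reactions, params)


def make_heterodimer(k_on=0.02, k_off=1.0, a0=50.0, b0=30.0) -> ReactionNetwork:
    """Reversible heterodimerization A + B <-> C."""
    species = [
        SpeciesDef("A", "cytoplasm", SpeciesRole.PROTEIN, a0),
        SpeciesDef("B", "cytoplasm", SpeciesRole.PROTEIN, b0),
        SpeciesDef("C", "cytoplasm", SpeciesRole.COMPLEX, 0.0),
    ]
    reactions = [
        Reaction("on", (("A", 1), ("B", 1)), (("C", 1),), "k_on"),
        Reaction("off", (("C", 1),), (("A", 1), ("B", 1)), "k_off"),
    ]
    params = ParameterSet(
        {"k_on": k_on, "k_off": k_off},
        {"k_on": "1/(Molecules*min)", "k_off": "1/min"},
    )
    return ReactionNetwork(species, COMPARTMENT_TABLE, reactions, params)


@pytest.fixture(scope="session")
def canonical():
    """Canonical network at 250 IU/mL (5,000 IFN molecules)."""
    return build_canonical_model(ifn_molecules=5000)


@pytest.fixture(scope="session")
def basal_network():
    return build_canonical_model(ifn_molecules=0)


@pytest.fixture(scope="session")
def noise_ensembles(canonical):
    """Full-model 32-h ensembles at extrinsic sigma 0 / 0.3 / 0.6, shared
    across tests.  The sigma 0 / 0.3 pair uses 600 repetitions so the
    two-sample KS sampling floor (1.36 * sqrt(2/n) ~ 0.079) sits safely
    below the response-conservation effect being measured."""
    out = {}
    for sigma, n_reps in ((0.0, 600), (0.3, 600), (0.6, 250)):
        out[sigma] = run_ensemble(
            canonical,
            n_reps=n_reps,
            t_grid=HOURLY_GRID,
            sampler=InitialConditionSampler(sigma=sigma),
            master_seed=2024,
        )
    return out


@pytest.fixture(scope="session")
def basal_ensemble(basal_network):
    """Unstimulated long run (48 h) for basal-average checks."""
    return run_ensemble(
        basal_network,
        n_reps=48,
        t_grid=np.arange(0.0, 2881.0, 60.0),
        master_seed=7,
    )


PANEL_CELLS = 150


@pytest.fixture(scope="session")
def snapshot_panel():
    """Synthetic flow-cytometry panel at the study conditions (all five
    doses, six time points), desk-scaled to 150 cells per time point."""
    from jakstat.synthetic import GeneratorConfig, generate_snapshots

    config = GeneratorConfig(
        doses_iu=(0.0, 10.0, 50.0, 250.0, 1250.0),
        times_h=(0.0, 8.0, 12.0, 16.0, 20.0, 32.0),
        cells_per_timepoint=PANEL_CELLS,
        master_seed=99,
    )
    return generate_snapshots(config)
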