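import numpy as np
import pytest

from triloop import fixtures as fx
from triloop.maxent import ReweightConfig, reweight
from triloop.structure import Ensemble
from triloop.synth import (EnsembleSpec, NOEDesign, StateSpec, build_a_form,
                           generate_ensemble, plant_noe_experiment)


@pytest.fixture(scope="session")
def ideal29():
    """Noise-free idealized conformation of the 29-nt hairpin."""
    return build_a_form(fx.secondary_structure("29"))


@pytest.fixture(scope="session")
def ideal29_ensemble(ideal29):
    return Ensemble(conformations=[ideal29])


@pytest.fixture(scope="session")
def two_state():
    """Two-state loop-opening ensemble with a planted NOE experiment:
    exactly 7 restraints violated at uniform weights, 13 satisfied."""
    spec = EnsembleSpec(
        structure=fx.secondary_structure("29"), n_snapshots=100, noise=0.1,
        states=[StateSpec("native", 0.3),
                StateSpec("open", 0.7, shift=(4.0, 2.0, 5.0), base_spin=40.0)])
    ens, truth = generate_ensemble(spec, seed=11)
    experiment = plant_noe_experiment(
        ens, truth, NOEDesign(n_violated=7, n_satisfied=13),
        candidate_residues=range(74, 84))
    return ens, truth, experiment


@pytest.fixture(scope="session")
def two_state_noiseless():
    """Noise-free two-state ensemble: within-state NOE values are exactly
    constant, so the feasibility boundary w* is exact."""
    spec = EnsembleSpec(
        structure=fx.secondary_structure("29"), n_snapshots=60, noise=0.0,
        states=[StateSpec("native", 0.25),
                StateSpec("open", 0.75, shift=(4.0, 2.0, 5.0), base_spin=40.0)])
    ens, truth = generate_ensemble(spec, seed=3)
    experiment = plant_noe_experiment(
        ens, truth, NOEDesign(n_violated=7, n_satisfied=10),
        candidate_residues=range(74, 84))
    return ens, truth, experiment


@pytest.fixture(scope="session")
def reweighted_two_state(two_state):
    _, _, experiment = two_state
    result = reweight(experiment.noe, experiment.noe_exp,
                      ReweightConfig(sigma=0.0))
    return result


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
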