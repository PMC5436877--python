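import numpy as np
import pytest

from lamellosc.io import bundle_model
from lamellosc.params import ModelTag, ModelVariant, ParameterSet


@pytest.fixture(scope="session")
def hybrid():
    """Calibrated hybrid-model bundle (params, variant)."""
    params, variant, _ = bundle_model("fig5_hybrid")
    return params, variant


@pytest.fixture(scope="session")
def model2():
    params, variant, _ = bundle_model("model2")
    return params, variant


@pytest.fixture(scope="session")
def model1b():
    params, variant, _ = bundle_model("model1b_osc")
    return params, variant


@pytest.fixture(scope="session")
def model1a(model1b):
    """Abundant-pool counterpart of the conserved competition bundle."""
    params, _ = model1b
    return params.with_(R_T=None, rho_T=None), ModelVariant(ModelTag.M1A)


def random_params(rng: np.random.Generator, variant: ModelVariant) -> ParameterSet:
    """A random but valid parameter set for any variant (test helper)."""
    hill = variant.hill_kinetics
    return ParameterSet(
        n=3 if hill else 1,
        delta=float(rng.uniform(0.5, 2.0)),
        b_R=float(rng.uniform(0.5, 6.0)),
        k_E=float(rng.uniform(0.0, 3.0)),
        gamma_E=float(rng.uniform(0.0, 3.0)),
        E0=float(rng.uniform(0.1, 1.0)) if hill else None,
        k_R=float(rng.uniform(0.01, 0.5)),
        gamma_R=float(rng.uniform(0.0, 1.0)),
        R0=float(rng.uniform(0.3, 2.0)) if hill else None,
        k_rho=float(rng.uniform(0.01, 0.5)),
        gamma_rho=float(rng.uniform(0.0, 1.5)),
        rho0=float(rng.uniform(0.3, 2.0)) if hill else None,
        eps=float(rng.uniform(0.02, 5.0)),
        eps2=float(rng.uniform(0.5, 20.0)) if variant.has_effectors else None,
        l_c=float(rng.uniform(0.0, 2.0)),
        R_T=float(rng.uniform(1.0, 3.0)) if variant.conserved else None,
        rho_T=float(rng.uniform(1.0, 3.0)) if variant.conserved else None,
    )


def random_state(rng: np.random.Generator, variant: ModelVariant,
                 params: ParameterSet) -> np.ndarray:
    """A random valid state (pools consistent for conserved variants)."""
    from lamellosc.models import state_labels
    labels = state_labels(variant)
    y = rng.uniform(0.05, 1.0, size=len(labels))
    if variant.conserved:
        i = labels.index("RI")
        fracs = rng.dirichlet([1, 1, 1])
        y[labels.index("R1")] = params.R_T * fracs[0]
        y[labels.index("R2")] = params.R_T * fracs[1]
        y[i] = params.R_T * fracs[2]
        fracs = rng.dirichlet([1, 1, 1])
        y[labels.index("rho1")] = params.rho_T * fracs[0]
        y[labels.index("rho2")] = params.rho_T * fracs[1]
        y[i + 1] = params.rho_T * fracs[2]
    return y
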