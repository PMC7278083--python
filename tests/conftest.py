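import numpy as np
import pytest

import misoflux as mf


@pytest.fixture(scope="session")
def toy_model():
    return mf.toy_model()


@pytest.fixture(scope="session")
def toy_targets():
    return [mf.EMU("F", (1, 2, 3, 4))]


@pytest.fixture(scope="session")
def toy_network(toy_model, toy_targets):
    return mf.trace_emus(toy_model, toy_targets)


@pytest.fixture(scope="session")
def toy_partition(toy_network, toy_targets):
    _, partition = mf.decompose(toy_network, toy_targets, lam=1)
    return partition


@pytest.fixture(scope="session")
def toy_system(toy_partition, toy_network, toy_model):
    return mf.assemble(toy_partition, toy_network, toy_model, backend="vector")


@pytest.fixture(scope="session")
def toy_system_tensor(toy_partition, toy_network, toy_model):
    return mf.assemble(toy_partition, toy_network, toy_model, backend="tensor")


@pytest.fixture(scope="session")
def toy_trajectory(toy_system):
    """Constant-step reference run at the default settings (h=0.005, 10 s)."""
    return mf.integrate_constant(toy_system, 0.005, 10.0)


@pytest.fixture(scope="session")
def toy_dense_reference(toy_system):
    """Dense constant-step reference (h=0.0005) for adaptive-step checks."""
    return mf.integrate_constant(toy_system, 0.0005, 10.0)


def make_generated(seed, n_metabolites=6, pool_range=(10.0, 100.0)):
    """A small generated fixture with turnover times tame enough for the
    constant-step integrator at h=0.005."""
    spec = mf.GeneratorSpec(
        n_metabolites=n_metabolites, seed=seed, pool_range=pool_range
    )
    model = mf.random_network(spec)
    targets = [mf.EMU(m, atoms) for m, atoms in model.measured_targets]
    network = mf.trace_emus(model, targets)
    _, partition = mf.decompose(network, targets, lam=1)
    return model, targets, network, partition


@pytest.fixture(scope="session")
def generated_cases():
    return [make_generated(seed) for seed in range(3)]


def single_pool_model(v=10.0, c=40.0):
    """One pool P fed by a fully labeled 1-carbon substrate at flux v:
    dm1/dt = (v/c)(1 - m1), so m1(t) = 1 - exp(-(v/c) t)."""
    model = mf.parse_model_text(
        "reaction\tstoichiometry\ttransition\n"
        "R_in\tS -> P\t#A -> #A\n"
        "R_out\tP -> P_OUT\t#A -> #A\n",
        f"""
fluxes: {{R_in: {v}, R_out: {v}}}
pool_sizes: {{P: {c}}}
labeling: {{S: {{"1": 1.0}}}}
measured: [P]
settings: {{t_end: 10, step: 0.005, lambda: 1}}
""",
    )
    return model


@pytest.fixture(scope="session")
def single_pool():
    model = single_pool_model()
    targets = [mf.EMU("P", (1,))]
    network = mf.trace_emus(model, targets)
    _, partition = mf.decompose(network, targets, lam=1)
    system = mf.assemble(partition, network, model)
    return model, system
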