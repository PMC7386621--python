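"""Shared fixtures: toy models and small twin datasets built at test time."""

import numpy as np
import pytest

from condassim.model import rvlm_model
from condassim.toys import leak_k_model, leak_model
from condassim.twin import build_step_protocol, make_twin_dataset, uniform_mesh


@pytest.fixture(scope="session")
def rvlm():
    model, table = rvlm_model()
    return model, table


@pytest.fixture(scope="session")
def leak():
    return leak_model()


@pytest.fixture(scope="session")
def leak_k():
    return leak_k_model()


@pytest.fixture(scope="session")
def leak_dataset(leak):
    model, table = leak
    proto = build_step_protocol([(20, 0), (40, 2000), (40, -1500)])
    return make_twin_dataset(model, table.p_true, proto, sigma=0.0, zeta=1, dt_base=0.05)


@pytest.fixture(scope="session")
def leak_problem(leak, leak_dataset):
    from condassim.collocation import SolverOptions, assemble_nlp

    model, table = leak
    mesh = uniform_mesh(len(leak_dataset.t) - 1, leak_dataset.dt_base, stride=4)
    return assemble_nlp(leak_dataset, mesh, model, table, SolverOptions())


@pytest.fixture(scope="session")
def leak_k_dataset(leak_k):
    model, table = leak_k
    # strong depolarizing steps make the rectifier kinetics identifiable
    proto = build_step_protocol(
        [(10, 0), (10, 8000), (10, -2000), (10, 12000), (10, 0), (10, 5000)]
    )
    return make_twin_dataset(model, table.p_true, proto, sigma=0.0, zeta=3, dt_base=0.05)
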