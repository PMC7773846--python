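"""Shared fixtures.

Heavy simulation campaigns are session-scoped so the suite runs each of
them exactly once; all are seeded and therefore reproducible.
"""
import numpy as np
import pytest

from metadhs import (
    MetadParams,
    build_complex,
    build_model,
    calibrate,
    equilibrate,
    run_metad_replica,
    run_unbiased,
)


@pytest.fixture(scope="session")
def human_system():
    system = build_complex("human-like", seed=7)
    return calibrate(system)


@pytest.fixture(scope="session")
def arch_system():
    system = build_complex("archaeal-like", seed=7)
    return calibrate(system)


@pytest.fixture(scope="session")
def human_model(human_system):
    return build_model(human_system)


@pytest.fixture(scope="session")
def arch_model(arch_system):
    return build_model(arch_system)


@pytest.fixture(scope="session")
def human_equil(human_system, human_model):
    return equilibrate(human_system, model=human_model, seed=1)


@pytest.fixture(scope="session")
def arch_equil(arch_system, arch_model):
    return equilibrate(arch_system, model=arch_model, seed=1)


@pytest.fixture(scope="session")
def small_campaigns(human_system, human_model, human_equil,
                    arch_system, arch_model, arch_equil):
    """Six metadynamics replicas per variant (analysis-level fixtures)."""
    params = MetadParams()
    out = {}
    for name, system, model, equil in (
            ("human-like", human_system, human_model, human_equil),
            ("archaeal-like", arch_system, arch_model, arch_equil)):
        outcomes = []
        for i in range(6):
            outcomes.append(run_metad_replica(
                system, params, seed=9000 + i, state=equil.state,
                model=model, replica_id=i))
        out[name] = outcomes
    return out


@pytest.fixture(scope="session")
def unbiased_campaigns(human_system, human_model, arch_system, arch_model):
    """Five 2000-ps unbiased production replicas per variant."""
    out = {}
    for name, system, model in (("human-like", human_system, human_model),
                                ("archaeal-like", arch_system, arch_model)):
        trajs = []
        for seed in range(1, 6):
            state = equilibrate(system, model=model, seed=seed).state
            trajs.append(run_unbiased(system, state, model=model))
        out[name] = trajs
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
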