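from dataclasses import replace

import pytest

import metalsense as ms


@pytest.fixture(scope="session")
def registry():
    return ms.build_registry(seed=0)


@pytest.fixture(scope="session")
def arsenic_circuit(registry):
    return ms.assemble_circuit(ms.Metal.ARSENIC, registry)


@pytest.fixture(scope="session")
def calibrated():
    """Calibrated single-cell parameters for all three sensors."""
    return {metal: ms.params_for(metal) for metal in ms.Metal}


@pytest.fixture
def quick_stationary():
    """Small, fast stationary scenario for unit tests (not the study size)."""
    base = ms.get_scenario("arsenic_stationary_threshold", seed=11)
    return replace(base, initial_pop=200, max_pop=200, t_end=60.0, name="quick_stationary")


@pytest.fixture
def quick_growing():
    """Small, fast growing scenario for unit tests."""
    base = ms.get_scenario("arsenic_growing_threshold", seed=13)
    return replace(
        base, initial_pop=60, max_pop=240, t_end=80.0, name="quick_growing"
    )
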