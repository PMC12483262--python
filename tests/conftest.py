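import pytest

from mitocomp import SimConfig, load_reference_table, make_ancestor, make_conspecific_panel


@pytest.fixture(scope="session")
def aegypti():
    return load_reference_table("aegypti")


@pytest.fixture(scope="session")
def albopictus():
    return load_reference_table("albopictus")


@pytest.fixture(scope="session")
def ancestor():
    """One deterministic synthetic mitogenome on the reference layout."""
    return make_ancestor(SimConfig(seed=42))


@pytest.fixture(scope="session")
def small_panel():
    """Six conspecific taxa radiating at depth 0.004 (aegypti-like)."""
    return make_conspecific_panel(6, 0.004, SimConfig(seed=11))
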