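import pytest

from ceatree import incremental_analysis, load_bundled_model, rollback


@pytest.fixture(scope="session")
def model():
    """The bundled vitamin D supplementation vs. no-intervention model."""
    return load_bundled_model()


@pytest.fixture(scope="session")
def base_results(model):
    """Deterministic rollback of both arms at base-case parameter values."""
    values = model.base_values()
    res_int = rollback(model.strategy(model.intervention), values)
    res_comp = rollback(model.strategy(model.comparator), values)
    return res_int, res_comp


@pytest.fixture(scope="session")
def base_incremental(base_results):
    res_int, res_comp = base_results
    return incremental_analysis(res_int, res_comp)
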