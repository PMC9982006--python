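import pytest

from gsmm.synth import make_geosmin_testbed, make_testbed_specs, make_toy_core_model


@pytest.fixture()
def toy_core():
    """Hand-solvable 8-reaction model with its glucose medium applied."""
    model, medium = make_toy_core_model()
    medium.apply(model)
    return model, medium


@pytest.fixture()
def testbed():
    """Default strain-design testbed with companion wild/over specs."""
    model, medium, key = make_geosmin_testbed()
    medium.apply(model)
    wild, over = make_testbed_specs(model, medium, key)
    return model, medium, key, wild, over
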