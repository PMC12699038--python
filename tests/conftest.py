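import numpy as np
import pytest

from saltax.biophysics import PassiveSpec
from saltax.cable_engine import CableSystem, build_default_model, settle
from saltax.morphology import MorphConfig, SegmentationRule, build_default_morphology


@pytest.fixture(scope="session")
def mini_config():
    """A short (~0.9 mm) axon config for fast engine tests."""
    return MorphConfig(
        axon_length_um=900.0,
        region_lengths_um={"Ctx": 300.0, "WM": 300.0, "Thal": 300.0},
        internode_length_um={"Ctx": 60.0, "WM": 80.0, "Thal": 60.0},
        apical_trunk_length_um=400.0,
        apical_tuft_length_um=250.0,
        n_basal=3,
        basal_length_um=120.0,
    )


@pytest.fixture(scope="session")
def mini_model(mini_config):
    return build_default_model(9, morph_config=mini_config)


@pytest.fixture(scope="session")
def mini_system(mini_model):
    return CableSystem(mini_model)


@pytest.fixture(scope="session")
def mini_rest(mini_system):
    return settle(mini_system, duration=400.0)


@pytest.fixture(scope="session")
def default_morphology():
    return build_default_morphology()


@pytest.fixture(scope="session")
def passive():
    return PassiveSpec()


@pytest.fixture(scope="session")
def seg_rule():
    return SegmentationRule()
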