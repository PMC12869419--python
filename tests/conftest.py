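"""Shared fixtures: small phantoms and scaled network configs."""

import numpy as np
import pytest

from perfsynth.network import NetworkConfig
from perfsynth.phantom import LesionSpec, PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def lesion_case():
    """256 px phantom with a mild-moderate lesion in the right hemisphere."""
    lesion = LesionSpec(center=(128.0, 170.0), core_axes=(10.0, 8.0),
                        penumbra_axes=(20.0, 16.0))
    spec = PhantomSpec(image_size=256, slice_count=11, lesion=lesion, seed=42)
    return make_phantom(spec, case_id="lesion42")


@pytest.fixture(scope="session")
def healthy_case():
    spec = PhantomSpec(image_size=256, slice_count=11, seed=7)
    return make_phantom(spec, case_id="healthy7")


@pytest.fixture(scope="session")
def small_case():
    """64 px phantom for fast end-to-end paths."""
    lesion = LesionSpec(center=(32.0, 44.0), core_axes=(3.0, 2.5),
                        penumbra_axes=(6.0, 4.5))
    spec = PhantomSpec(image_size=64, slice_count=11, lesion=lesion, seed=11)
    return make_phantom(spec, case_id="small11")


@pytest.fixture(scope="session")
def tiny_net_cfg():
    return NetworkConfig(image_size=32, base_width=8)


@pytest.fixture(scope="session")
def small_net_cfg():
    return NetworkConfig(image_size=64, base_width=16)
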