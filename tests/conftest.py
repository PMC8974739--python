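import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import xenovent as xv
from xenovent.phantom import GAS_REGIONS

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def pre_protocol():
    return xv.build_protocol("pre_fess")


@pytest.fixture(scope="session")
def post_protocol():
    return xv.build_protocol("post_fess")


@pytest.fixture(scope="session")
def clean_spec():
    """Default pre-surgery phantom without noise."""
    return xv.PhantomSpec.for_variant("pre_fess", noise_sigma_hu=0.0)


@pytest.fixture(scope="session")
def clean_traces(clean_spec, pre_protocol):
    return xv.simulate_concentrations(clean_spec, pre_protocol)


@pytest.fixture(scope="session")
def clean_labels(clean_spec):
    return xv.build_label_map(clean_spec)


@pytest.fixture(scope="session")
def clean_series(clean_spec, clean_traces, pre_protocol, clean_labels):
    """Noise-free three-channel render of the default pre-surgery phantom."""
    return xv.render_series(clean_spec, clean_traces, pre_protocol, labels=clean_labels)


@pytest.fixture(scope="session")
def gas_rois(clean_labels):
    return xv.rois_from_labels(clean_labels, [r.name for r in GAS_REGIONS])


@pytest.fixture(scope="session")
def pre_result(clean_series, gas_rois, pre_protocol):
    """Full analysis of the noise-free pre-surgery run."""
    return xv.analyze_series(clean_series, gas_rois, pre_protocol, variant="pre_fess")


@pytest.fixture(scope="session")
def post_bundle(post_protocol):
    """Noise-free post-surgery simulation, mixed channel, plus its analysis."""
    spec = xv.PhantomSpec.for_variant("post_fess", noise_sigma_hu=0.0)
    series, traces, labels = xv.simulate_phantom(spec, post_protocol, channels=("mixed",))
    rois = xv.rois_from_labels(labels, [r.name for r in GAS_REGIONS])
    result = xv.analyze_series(series, rois, post_protocol, variant="post_fess")
    return spec, series, traces, result


@pytest.fixture(scope="session")
def small_spec():
    """Coarse grid for fast rendering-heavy tests."""
    return xv.PhantomSpec.for_variant(
        "pre_fess", grid_shape=(32, 32, 24), noise_sigma_hu=0.0
    )
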