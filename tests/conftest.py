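import numpy as np
import pytest

from hasm import (
    HeatmapNoiseParams,
    ShapeModel,
    SpineTemplateParams,
    generate_dataset,
    generate_spine,
    simulate_heatmaps,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def template_params():
    return SpineTemplateParams(n_images=60)


@pytest.fixture(scope="session")
def train_shapes(template_params):
    return generate_dataset(np.random.default_rng(7), template_params)


@pytest.fixture(scope="session")
def shape_model(train_shapes):
    return ShapeModel.fit(train_shapes)


@pytest.fixture(scope="session")
def clean_truth():
    params = SpineTemplateParams(n_images=1, spondylolisthesis_fraction=0.0)
    return generate_dataset(np.random.default_rng(11), params)[0]


@pytest.fixture(scope="session")
def clean_stack(clean_truth):
    return simulate_heatmaps(clean_truth, HeatmapNoiseParams(), np.random.default_rng(12))


@pytest.fixture
def one_spine(rng):
    return generate_spine(rng, SpineTemplateParams())
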