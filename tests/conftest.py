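import pytest

from striocompart.synth import (
    SynthesisConfig, EffectTable, generate_striosome_mask, render_section,
)


@pytest.fixture(scope="session")
def effects() -> EffectTable:
    return EffectTable.default()


@pytest.fixture(scope="session")
def small_config() -> SynthesisConfig:
    return SynthesisConfig(image_height_px=192, image_width_px=256,
                           striosome_scale_px=16.0, n_fiber_bundles=3,
                           n_vessels=2, seed=7)


@pytest.fixture(scope="session")
def small_labels(small_config):
    return generate_striosome_mask(small_config)


@pytest.fixture(scope="session")
def noiseless_config() -> SynthesisConfig:
    return SynthesisConfig(image_height_px=192, image_width_px=256,
                           striosome_scale_px=16.0, noise_sd=0.0,
                           n_fiber_bundles=2, n_vessels=1, seed=11)


@pytest.fixture(scope="session")
def noiseless_render(noiseless_config, effects):
    labels = generate_striosome_mask(noiseless_config)
    section = render_section(labels, effects, "PDE10A", "WT", 3,
                             noiseless_config)
    return section, labels
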