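import dataclasses

import pytest

from plotspec import SceneConfig, simulate_scene

#: desk-scale ground sample distance used by most tests; the generative model
#: is resolution-independent, so a coarser grid only reduces pixel counts
COARSE_GSD = 0.08


@pytest.fixture(scope="session")
def coarse_config():
    return SceneConfig(gsd=COARSE_GSD, seed=11)


@pytest.fixture(scope="session")
def coarse_scene(coarse_config):
    """Full 6-stage simulated trial at desk-scale resolution."""
    return simulate_scene(coarse_config, keep_true_reflectance=True)


def noiseless(config: SceneConfig, **overrides) -> SceneConfig:
    """Copy of a config with every imaging noise source (incl. DN quantization)
    switched off; latent plot-level variability is kept unless overridden."""
    base = dict(
        dn_noise_sd=0.0,
        refl_noise_sd=0.0,
        mixing_sd=0.0,
        quantize_dn=False,
    )
    base.update(overrides)
    return dataclasses.replace(config, **base)


@pytest.fixture(scope="session")
def noiseless_scene(coarse_config):
    return simulate_scene(noiseless(coarse_config), keep_true_reflectance=True)


def homogeneous_vigor(config: SceneConfig) -> SceneConfig:
    """Noiseless scene with identical vigor on every plot: the VARI histogram
    then has exactly one soil and one canopy value (two disjoint clusters)."""
    return noiseless(
        config,
        vigor_params={
            "intercept": 0.5, "span": 0.0, "gamma": 1.0,
            "variety_offsets": (0.0, 0.0, 0.0), "noise_sd": 0.0,
        },
    )
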