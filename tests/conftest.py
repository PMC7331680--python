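import numpy as np
import pytest

from n400kit import EffectSpec, Montage, NoiseSpec, simulate_subject


@pytest.fixture(scope="session")
def montage():
    return Montage.standard_64()


@pytest.fixture(scope="session")
def small_channels(montage):
    """Eight scalp channels around the vertex for reduced simulations."""
    return tuple(montage.neighbourhood("Cz", 8))


def make_null_subject(montage, channels, seed, n_pairs=20, srate=50.0,
                      window=(-100.0, 900.0)):
    """Reduced-scale subject with zero condition effect (50 samples)."""
    ep, _ = simulate_subject(
        n_pairs,
        montage=montage,
        channels=channels,
        srate=srate,
        window=window,
        seed=seed,
        effect=EffectSpec(amplitude=0.0),
    )
    return ep


def make_effect_subject(montage, channels, seed, amplitude=-4.0, n_pairs=20,
                        srate=50.0, window=(-100.0, 900.0), center="Cz",
                        latency=400.0, noise=None):
    ep, gt = simulate_subject(
        n_pairs,
        montage=montage,
        channels=channels,
        srate=srate,
        window=window,
        seed=seed,
        effect=EffectSpec(amplitude=amplitude, peak_latency=latency,
                          topography_center=center),
        noise=noise if noise is not None else NoiseSpec(),
    )
    return ep, gt
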