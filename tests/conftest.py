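import numpy as np
import pytest

from fluoromix import (
    ChannelSet,
    PhantomConfig,
    SpectralChannel,
    SpectralStack,
    Spectrum,
    SpectrumLibrary,
)
from fluoromix.spectra import NFE, RADIANCE


@pytest.fixture
def channelset4():
    """The 4-channel protocol with non-trivial correction factors."""
    factors = (1.0, 0.8, 1.25, 2.0)
    return ChannelSet(
        tuple(
            SpectralChannel(ex, em, correction_factor=f)
            for (ex, em), f in zip(
                ((465, 540), (465, 580), (535, 600), (570, 620)), factors
            )
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


def make_stack(pixels, channelset, units=NFE):
    """Stack from an (L,) vector (1×1 image) or an (L, H, W) array."""
    data = np.asarray(pixels, dtype=float)
    if data.ndim == 1:
        data = data[:, None, None]
    return SpectralStack(data, channelset, units=units)


@pytest.fixture
def library4(channelset4):
    """A well-conditioned 2-endmember library on 4 channels."""
    a = Spectrum(np.array([0.62, 0.54, 0.45, 0.34]), "autofluorescence").unit()
    d = Spectrum(np.array([0.05, 0.15, 0.35, 0.92]), "DsRed").unit()
    return SpectrumLibrary([a, d])


@pytest.fixture
def noiseless_phantom():
    return PhantomConfig(height=48, width=48, noise_model="none", seed=7)
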