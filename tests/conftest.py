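import numpy as np
import pytest

from fluoroquant import MultiChannelImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def as_image(channels: dict, pixel_size_um: float = 0.1, condition: str = "") -> MultiChannelImage:
    """Wrap named 2-D arrays into a MultiChannelImage."""
    names = tuple(channels)
    stack = np.stack([np.asarray(channels[n], dtype=np.float64) for n in names])
    return MultiChannelImage(
        pixels=stack, channel_names=names, pixel_size_um=pixel_size_um, condition=condition
    )


def gaussian_blob(shape, center, sigma, amplitude=100.0):
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    return amplitude * np.exp(
        -((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2.0 * sigma**2)
    )
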