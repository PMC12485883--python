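import numpy as np
import pytest

from memsheet import ChannelImage, SquareROI


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def noise_image(seed: int, shape=(64, 64), pixel_size_nm=83.3, label="ch",
                lam=50.0) -> ChannelImage:
    r = np.random.default_rng(seed)
    return ChannelImage(
        r.poisson(lam, shape).astype(float), pixel_size_nm, label
    )


@pytest.fixture
def full_roi():
    def make(image: ChannelImage) -> SquareROI:
        assert image.shape[0] == image.shape[1]
        return SquareROI(0, 0, image.shape[0])

    return make
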