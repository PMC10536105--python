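import numpy as np
import pytest

from erphot.frames import PhotometricFrame
from erphot.synth import ForwardModel


@pytest.fixture(scope="session")
def reference_model() -> ForwardModel:
    return ForwardModel.from_reference()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230906)


def make_frame(pixels, bit_depth=8, thickness=2.0, power=4.2, mode="transmitted",
               site=1, capture=1) -> PhotometricFrame:
    return PhotometricFrame(
        pixels=np.asarray(pixels, dtype=float),
        bit_depth=bit_depth,
        thickness_mm=thickness,
        power_mW=power,
        mode=mode,
        site_index=site,
        capture_index=capture,
    )
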