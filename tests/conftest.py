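import numpy as np
import pytest

from microqc import AcquisitionMeta, ChannelMeta, Modality


@pytest.fixture
def gfp_channel():
    return ChannelMeta("gfp", 488.0, 525.0)


@pytest.fixture
def dapi_channel():
    return ChannelMeta("dapi", 405.0, 450.0)


@pytest.fixture
def wf_meta(gfp_channel):
    """High-NA oil wide-field setup, Nyquist-sampled laterally and axially."""
    return AcquisitionMeta(
        modality=Modality.WF,
        na=1.4,
        refractive_index=1.515,
        pixel_size_xy=0.05,
        z_step=0.1,
        channels=(gfp_channel,),
        bit_depth=16,
    )


@pytest.fixture
def two_channel_meta(dapi_channel, gfp_channel):
    return AcquisitionMeta(
        modality=Modality.WF,
        na=1.4,
        refractive_index=1.515,
        pixel_size_xy=0.05,
        z_step=0.1,
        channels=(dapi_channel, gfp_channel),
        bit_depth=16,
    )
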