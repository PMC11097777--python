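import pytest

from psaeegnet import NetworkConfig, PSAConfig


@pytest.fixture()
def tiny_config():
    """A scaled-down architecture for fast structural / gradient tests."""
    return NetworkConfig(
        n_channels=8, n_samples=24, temporal_filters=4, temporal_kernel=7,
        depth_multiplier=2, separable_kernel=4, pool_size=3,
        pool_out_lengths=(8, 3), dropout_p=0.0,
        psa_psfe=PSAConfig((1, 3, 5, 7)), psa_dtfe=PSAConfig((1, 3, 5, 7)))
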