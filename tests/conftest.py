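import pytest

from cpfr import SynthConfig, load_config, simulate_recording


@pytest.fixture()
def default_config():
    return load_config(None)


@pytest.fixture()
def noiseless_recording():
    """Factory: clean piecewise-linear recording with exact programmed gains."""

    def make(frequency_hz=0.05, **overrides):
        cfg = SynthConfig.noiseless(frequency_hz, **overrides)
        return simulate_recording(cfg)

    return make
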