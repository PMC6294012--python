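import numpy as np
import pytest

from memstdp import DeviceParams, NeuronParams, ProtocolConfig, SimConfig


@pytest.fixture
def nominal_device():
    return DeviceParams()


@pytest.fixture
def neuron():
    return NeuronParams()


@pytest.fixture
def tiny_protocol():
    """Three frames, one epoch: small enough for brute-force cross-checks."""
    return ProtocolConfig(n_epochs=1, frames_per_epoch=3, p_spike=1.0,
                          t_jitter_max=5.0, offset_max=27.0, seed=11)


def sync_noise_groups(cfg: ProtocolConfig) -> dict:
    sync = list(cfg.synchronized_rows)
    return {"sync": sync, "noise": [r for r in range(cfg.n_rows) if r not in sync]}
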