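import numpy as np
import pytest

from cnibp.simulate import (ChannelConfig, DynamicsConfig,
                            generate_bp_trajectory, synthesize_recording)

CLEAN = ChannelConfig(catheter_filter="identity", noise=False)


@pytest.fixture(scope="session")
def flat_recording():
    """60 s flat 120/80 record, identity catheter, noise off."""
    traj = generate_bp_trajectory(60, "flat", seed=1)
    return synthesize_recording(traj, channel_config=CLEAN, seed=1)


@pytest.fixture(scope="session")
def induction_recording():
    """120 s induction-dynamics record, identity catheter, noise off."""
    traj = generate_bp_trajectory(120, "induction", seed=7)
    return synthesize_recording(traj, channel_config=CLEAN, seed=7)


@pytest.fixture(scope="session")
def noisy_recording():
    """300 s flat record with default channel models and noise."""
    traj = generate_bp_trajectory(300, "flat", seed=4)
    return synthesize_recording(traj, seed=4)
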