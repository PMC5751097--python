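import pytest

from cnmotion import BasisConfig, SynthSpec, generate_trajectory


@pytest.fixture(scope="session")
def two_center_clip():
    """Noise-free 10 s, 120 Hz clip from two centers at 0.5 / 1.3 Hz,
    25 RBF satellites, one marker — plus its ground truth."""
    spec = SynthSpec(seed=11, n_centers=2, freqs_hz=(0.5, 1.3), n_satellites=25)
    traj, truth = generate_trajectory(spec)
    return traj, truth


@pytest.fixture(scope="session")
def four_marker_clip():
    """Noise-free 4-marker clip sharing one oscillator bank."""
    spec = SynthSpec(
        seed=7, n_centers=2, freqs_hz=(0.5, 1.3), n_satellites=25, n_markers=4
    )
    traj, truth = generate_trajectory(spec)
    return traj, truth


@pytest.fixture()
def rbf25():
    return BasisConfig(family="rbf", n_satellites=25)
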