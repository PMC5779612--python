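import numpy as np
import pytest

from flysleep.synth import ArenaSpec, LabeledTrajectory, VideoParams, render_frames


def make_scripted_trajectory(jumps, dt=0.2, hold=3.0, x0=10.0, y=5.0, tube=65.0):
    """Piecewise-constant trajectory: the fly sits at x0 and performs the
    given displacements (mm) one per `hold` seconds."""
    n_steps = len(jumps) + 1
    t = np.arange(0.0, n_steps * hold, dt)
    x = np.full(len(t), x0)
    pos = x0
    for k, d in enumerate(jumps):
        pos += d
        x[t >= (k + 1) * hold] = pos
    return LabeledTrajectory(
        t, x, np.full(len(t), y), np.zeros(len(t), bool), [], tube_length_mm=tube
    )


@pytest.fixture
def arena():
    return ArenaSpec(px_per_mm=4.0, frame_rate=5.0)


@pytest.fixture
def clean_video():
    return VideoParams(noise_sigma=0.0)


@pytest.fixture
def walk_stack(arena, clean_video):
    """Noise-free rendered stack of a 5-jump walk, plus its trajectory."""
    traj = make_scripted_trajectory([5.0, 5.0, 5.0, -5.0, 5.0])
    return render_frames(traj, arena, clean_video, seed=0), traj
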