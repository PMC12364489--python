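import numpy as np
import pytest

import sensilla as sl


@pytest.fixture(scope="session")
def three_unit_cfg() -> sl.SsrSimConfig:
    """Three units with distinct amplitudes; unit a responds to the stimulus."""
    return sl.SsrSimConfig(
        n_units=3, unit_amplitudes=(1.5, 1.0, 0.6),
        spontaneous_rates=(6.87, 5.0, 4.0), stim_gain=(10.0, 1.0, 1.0),
        duration=5.0, stim_onset=2.0, noise_sd=0.03, seed=1)


@pytest.fixture(scope="session")
def three_unit_recording(three_unit_cfg):
    return sl.simulate_ssr_trace(three_unit_cfg)


@pytest.fixture(scope="session")
def loop_trajectory():
    """200 atoms, 500 frames, atoms 160-179 twice as mobile as the rest."""
    cfg = sl.TrajectorySimConfig(
        n_atoms=200, n_frames=500, base_sigma=0.5,
        loop_atom_indices=tuple(range(160, 180)), loop_sigma=1.0, seed=11)
    traj, sigma = sl.simulate_trajectory(cfg)
    return traj, sigma, cfg


def match_spikes(truth: sl.SpikeTrain, detected: sl.SpikeTrain,
                 tol: float = 0.0015) -> tuple[int, int, int]:
    """Greedy time matching; returns (true positives, missed, spurious)."""
    used = np.zeros(len(detected), dtype=bool)
    tp = 0
    for t in truth.times:
        if len(detected) == 0:
            break
        d = np.abs(detected.times - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol:
            used[j] = True
            tp += 1
    return tp, len(truth) - tp, int((~used).sum())
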