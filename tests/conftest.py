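import numpy as np
import pytest

from gazestab.core import Modality, Plane, StimulusProtocol
from gazestab.synthetic import (
    GroundTruth,
    make_emg_trial,
    make_head_motion,
    make_psp_train,
    make_vor_eye_trace,
    nystagmus_fixture,
    vor_fixture,
)


@pytest.fixture(scope="session")
def roll_fixture_clean():
    """Noise-free roll-plane VOR fixture (eye, head profile, ground truth)."""
    return vor_fixture("roll", seed=1, noise_deg=0.0)


@pytest.fixture(scope="session")
def roll_fixture_noisy():
    return vor_fixture("roll", seed=1, noise_deg=0.05)


@pytest.fixture(scope="session")
def nystagmus_clean():
    """Noise-free full-rotation yaw fixture with ground-truth segmentation."""
    return nystagmus_fixture(seed=1, noise_deg=0.0)


@pytest.fixture(scope="session")
def emg_pair():
    """Same-seed VES and VISVES trials with ground truth."""
    ves = make_emg_trial(
        StimulusProtocol(Modality.VES, Plane.ROLL, 22.7, 48.7), seed=0
    )
    visves = make_emg_trial(
        StimulusProtocol(Modality.VISVES, Plane.ROLL, 22.7, 48.7), seed=0
    )
    return ves, visves


@pytest.fixture(scope="session")
def psp_clean():
    return make_psp_train(noise_mv=0.0, amplitudes_mv=1.0, seed=0)


def spike_f1(detected: np.ndarray, truth: np.ndarray, tol_s: float = 1e-3) -> float:
    """Greedy nearest-match F1 between detected and ground-truth spike times."""
    used = np.zeros(truth.size, dtype=bool)
    tp = 0
    for t in detected:
        if truth.size == 0:
            break
        d = np.abs(truth - t)
        j = int(np.argmin(d))
        if d[j] <= tol_s and not used[j]:
            used[j] = True
            tp += 1
    precision = tp / max(detected.size, 1)
    recall = tp / max(truth.size, 1)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
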