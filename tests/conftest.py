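import dataclasses

import numpy as np
import pytest

from walknet import synthgen

EMG_FS = 2000.0
KIN_FS = 70.0


def planted_envelope_matrix(seed, sc=6, n=200, noise=0.05, m_true=5):
    """Planted rank-m_true envelope matrix (SC*N x 26) + true weights."""
    rng = np.random.default_rng(seed)
    W, peaks, widths = synthgen.default_planted_synergies(m_true, seed)
    phase = np.tile(np.arange(n) / n, sc)
    A = np.stack(
        [synthgen.planted_activation(phase, peaks[s], widths[s]) for s in range(m_true)]
    )
    X = (W @ A).T + rng.normal(0.0, noise, (sc * n, 26))
    return np.clip(X, 0.0, None), W, A


@pytest.fixture(scope="session")
def planted_X():
    return planted_envelope_matrix(seed=0)


@pytest.fixture(scope="session")
def trial_gt():
    """Ground truth for a 22-stride trial at a 1.4 s stride period."""
    st = np.arange(0, 22 * 1.4 + 0.1, 1.4)
    gt = synthgen.make_ground_truth(seed=5)
    return dataclasses.replace(gt, stride_times=st)


@pytest.fixture(scope="session")
def small_recordings():
    """Four-trial synthetic study reused across tests (session-scoped)."""
    cfg = {"n_subjects": 2, "speeds": [1.0, 4.0], "n_strides": 12, "seed": 11}
    recordings, gt = synthgen.generate_study(cfg)
    return recordings, gt
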