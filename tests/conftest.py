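import numpy as np
import pytest

from orgephys.geometry import generate_array
from orgephys.synth import generate_ef


@pytest.fixture(scope="session")
def grid3x3():
    return generate_array(3, 3)


@pytest.fixture(scope="session")
def grid10():
    return generate_array(10, 10)


def make_family_efs(array, kinds, n_each, noise_sd=0.5, seed0=0, fs=20_000.0):
    """EFs on the center electrode of ``array``, one waveform family per kind."""
    efs = []
    u = 0
    center = array.electrode_id[len(array) // 2]
    for kind in kinds:
        for _ in range(n_each):
            efs.append(
                generate_ef(
                    array,
                    [center],
                    0.4,
                    peak_amp=80.0,
                    noise_sd=noise_sd,
                    unit_id=u,
                    template_kind=kind,
                    seed=seed0 + u,
                    fs=fs,
                )
            )
            u += 1
    return efs


def purity(labels, truth):
    """Fraction of points whose cluster's majority family matches their own."""
    labels, truth = np.asarray(labels), np.asarray(truth)
    correct = 0
    for c in np.unique(labels):
        members = truth[labels == c]
        correct += np.bincount(members).max()
    return correct / labels.size
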