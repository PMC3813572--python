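"""Shared fixtures: frozen MVAR fixture systems and a minimal EDF writer."""
import numpy as np
import pytest

from dtfnet import MultichannelRecording, SimulationConfig, simulate_mvar_network

# Stated stable order-3, 5-channel fixture system used by the recovery tests:
# diagonal AR terms plus a handful of directed cross-couplings; companion
# spectral radius ~0.62.
FIXTURE_A3 = np.zeros((3, 5, 5))
FIXTURE_A3[0] = np.diag([0.45, 0.35, 0.40, 0.30, 0.42])
FIXTURE_A3[0, 1, 0] = 0.40
FIXTURE_A3[0, 2, 1] = -0.35
FIXTURE_A3[1, 3, 2] = 0.30
FIXTURE_A3[2, 4, 0] = 0.25
FIXTURE_A3[1, 0, 4] = -0.20

# Stable order-2, 3-channel system for order-selection and spectral tests.
FIXTURE_A2 = np.array([
    [[0.5, 0.2, 0.0],
     [0.0, 0.4, 0.3],
     [0.2, 0.0, 0.3]],
    [[-0.2, 0.0, 0.1],
     [0.1, -0.25, 0.0],
     [0.0, 0.15, -0.2]],
])


@pytest.fixture(scope="session")
def fixture_a3():
    return FIXTURE_A3.copy()


@pytest.fixture(scope="session")
def fixture_a2():
    return FIXTURE_A2.copy()


@pytest.fixture()
def white_recording():
    rng = np.random.default_rng(42)
    return MultichannelRecording(rng.standard_normal((2048, 3)), 128.0,
                                 ["Fp1", "Cz", "Pz"])


@pytest.fixture(scope="session")
def mvar_recording():
    rec, truth = simulate_mvar_network(FIXTURE_A3, np.eye(5),
                                       SimulationConfig(4096, 128.0, seed=11))
    return rec, truth


def write_minimal_edf(path, data, sampling_rate, labels,
                      samples_per_record=None):
    """Write a bare-bones EDF file (int16, one data record per second).

    ``samples_per_record`` overrides the per-signal samples/record fields to
    let tests construct mixed-rate files.
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    spr = int(sampling_rate)
    n_records = n // spr
    if samples_per_record is None:
        samples_per_record = [spr] * k

    phys_min, phys_max = data.min() - 1e-6, data.max() + 1e-6
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)

    def pad(text, width):
        return f"{text:<{width}}"[:width].encode("ascii")

    header = b"".join([
        pad("0", 8), pad("X", 80), pad("X", 80),
        pad("01.01.01", 8), pad("00.00.00", 8),
        pad(str(256 * (1 + k)), 8), pad("", 44),
        pad(str(n_records), 8), pad("1", 8), pad(str(k), 4),
    ])
    sig = b"".join(pad(lab, 16) for lab in labels)
    sig += b"".join(pad("", 80) for _ in labels)          # transducer
    sig += b"".join(pad("uV", 8) for _ in labels)
    sig += b"".join(pad(f"{phys_min:.3f}", 8) for _ in labels)
    sig += b"".join(pad(f"{phys_max:.3f}", 8) for _ in labels)
    sig += b"".join(pad(str(dig_min), 8) for _ in labels)
    sig += b"".join(pad(str(dig_max), 8) for _ in labels)
    sig += b"".join(pad("", 80) for _ in labels)          # prefilter
    sig += b"".join(pad(str(s), 8) for s in samples_per_record)
    sig += b"".join(pad("", 32) for _ in labels)

    digital = np.round((data - phys_min) * scale + dig_min).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header + sig)
        for rec_i in range(n_records):
            block = digital[rec_i * spr:(rec_i + 1) * spr]
            for c in range(k):
                fh.write(block[:, c].tobytes())
    return path
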