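import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from ecgcompress.io import ECGRecord, write_wfdb_record
from ecgcompress.synthetic import SyntheticBeatSpec, generate_dataset


@pytest.fixture(scope="session")
def low_noise_spec() -> SyntheticBeatSpec:
    return SyntheticBeatSpec(seed=0)


@pytest.fixture(scope="session")
def small_dataset(low_noise_spec):
    """400 beats, 100 per class, 260 samples."""
    return generate_dataset(low_noise_spec, n_per_class=100)


@pytest.fixture(scope="session")
def tiny_dataset(low_noise_spec):
    """64 beats, 16 per class — smoke-training size."""
    return generate_dataset(low_noise_spec, n_per_class=16)


@pytest.fixture()
def wfdb_record_dir(tmp_path):
    """A directory with one synthetic single-channel WFDB record.

    Ten annotated beats: positive triangular peaks every 300 samples starting
    at sample 200, alternating N and V symbols, plus one rhythm mark.
    """
    rng = np.random.default_rng(7)
    n = 3400
    signal = 0.05 * rng.standard_normal(n)
    peaks = [200 + 300 * i for i in range(10)]
    for p in peaks:
        signal[p - 3 : p + 4] += np.array([0.2, 0.5, 0.9, 1.2, 0.9, 0.5, 0.2])
    annotations = []
    for i, p in enumerate(peaks):
        annotations.append((p, "N" if i % 2 == 0 else "V"))
    annotations.insert(3, (annotations[2][0] + 50, "+"))  # rhythm change mark
    record = ECGRecord("synth01", 360.0, signal, annotations)
    write_wfdb_record(str(tmp_path / "synth01"), record)
    return tmp_path
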