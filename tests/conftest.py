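import numpy as np
import pytest

from sabgal.batch import FieldRecord
from sabgal.signal import SignalMeasurement


def make_record(field_id, group, integrated_density, nuclei_count, qc_status="auto",
                mean_nucleus_area=None, replicate=None):
    """Build a FieldRecord with a consistent SignalMeasurement for tests."""
    area = max(1, int(integrated_density // 50))
    sig = SignalMeasurement(area, float(integrated_density),
                            float(integrated_density) / area)
    idpc = None
    if nuclei_count and nuclei_count >= 1:
        idpc = integrated_density / nuclei_count
    return FieldRecord(
        field_id=field_id,
        group=group,
        signal=sig,
        nuclei_count=nuclei_count,
        id_per_cell=idpc,
        qc_status=qc_status,
        mean_nucleus_area=mean_nucleus_area,
        replicate=replicate,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_rgb(rng):
    """Factory for small random uint8 RGB images."""

    def _make(h=16, w=16):
        return rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)

    return _make
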