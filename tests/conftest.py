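import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from laneseq.count_data import CountMatrix, LaneInfo

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_matrix() -> CountMatrix:
    counts = np.array([
        [12, 10, 30, 28],
        [0, 0, 0, 0],
        [5, 7, 2, 1],
        [100, 90, 210, 200],
        [1, 0, 3, 2],
        [40, 44, 38, 36],
        [7, 7, 7, 7],
        [0, 2, 0, 5],
    ])
    lengths = np.array([500, 300, 1200, 2000, 250, 800, 1000, 400])
    return CountMatrix(
        [f"g{i}" for i in range(8)], ["A1", "A2", "B1", "B2"], counts,
        gene_lengths=lengths,
    )


@pytest.fixture
def toy_lanes(toy_matrix: CountMatrix) -> LaneInfo:
    totals = toy_matrix.lane_totals()
    return LaneInfo.from_records([
        ("A1", "A", "F1", "prepA", int(totals[0])),
        ("A2", "A", "F2", "prepA", int(totals[1])),
        ("B1", "B", "F1", "prepB", int(totals[2])),
        ("B2", "B", "F2", "prepB", int(totals[3])),
    ])
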