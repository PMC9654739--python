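import numpy as np
import pytest

from olivesort import sorter_eval

# Printed sorter-stream cross-tabulation for the calibrated run: rows are the
# sorter's output streams, columns the conveyor classes in
# (Bad Black, Bad Green, Good Black, Good Green, Top Green) order.
TABLE5_ROWS = ("Black slow", "Green slow", "Black fast", "Green fast")
TABLE5_COUNTS = np.array(
    [
        [187, 81, 531, 281, 21],
        [28, 266, 63, 132, 283],
        [60, 36, 262, 127, 10],
        [10, 89, 25, 67, 153],
    ]
)

# Non-calibrated run of the same lot; its printed Black-fast total (495)
# disagrees with the row sum (494), which the evaluator must flag.
TABLE6_COUNTS = np.array(
    [
        [392, 80, 333, 269, 27],
        [44, 221, 48, 130, 329],
        [88, 54, 228, 115, 9],
        [12, 83, 25, 51, 173],
    ]
)
TABLE6_STATED_TOTALS = {
    "Black slow": 1101,
    "Green slow": 772,
    "Black fast": 495,
    "Green fast": 344,
}


@pytest.fixture
def table5():
    return sorter_eval.StreamCrossTab(
        TABLE5_ROWS, sorter_eval.CLASS_ORDER, TABLE5_COUNTS.copy()
    )


@pytest.fixture
def table6():
    return sorter_eval.StreamCrossTab(
        TABLE5_ROWS, sorter_eval.CLASS_ORDER, TABLE6_COUNTS.copy()
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
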