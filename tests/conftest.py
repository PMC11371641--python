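import numpy as np
import pytest

from epsckit import synthgen as sg


def match_events(true_times, detected_times, tol=0.002):
    """Greedy one-to-one matching of detected to true event times.

    Returns (recall, precision) with a ``tol``-second matching tolerance.
    """
    true_times = np.asarray(true_times)
    detected_times = np.asarray(detected_times)
    used = set()
    tp = 0
    for t in true_times:
        if detected_times.size == 0:
            break
        d = np.abs(detected_times - t)
        j = int(np.argmin(d))
        if d[j] < tol and j not in used:
            used.add(j)
            tp += 1
    recall = tp / true_times.size if true_times.size else float("nan")
    precision = tp / detected_times.size if detected_times.size else float("nan")
    return recall, precision


@pytest.fixture
def wt_epsc_config():
    return sg.preset_config("WT", "epsc", seed=1)


@pytest.fixture
def kernel():
    return sg.make_mini_kernel(20.0, 0.5, 3.0, 10_000.0)
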