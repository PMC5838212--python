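import numpy as np
import pandas as pd
import pytest

from evcargo.counts import MiRNACountMatrix


def toy_matrix(values: dict, classes: dict, conditions: dict, state="raw"):
    """Small count matrix from plain dicts (columns = samples)."""
    df = pd.DataFrame(values)
    return MiRNACountMatrix(
        values=df,
        probe_class=pd.Series(classes),
        conditions=pd.Series(conditions),
        state=state,
    )


def match_events(true_times, found_times, tol=0.0005):
    """Greedy one-to-one matching of event times within +/- tol seconds.

    Returns (n_matched, n_true, n_found).
    """
    true_times = sorted(true_times)
    found_times = sorted(found_times)
    i = j = matched = 0
    while i < len(true_times) and j < len(found_times):
        dt = found_times[j] - true_times[i]
        if abs(dt) <= tol:
            matched += 1
            i += 1
            j += 1
        elif dt < 0:
            j += 1
        else:
            i += 1
    return matched, len(true_times), len(found_times)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
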