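import numpy as np
import pandas as pd
import pytest

from cogfrail import PanelDataset, SimulationConfig, build_intensity_matrix, simulate_cohort
from cogfrail.reference import REFERENCE_INTENSITIES


@pytest.fixture(scope="session")
def reference_Q():
    return build_intensity_matrix(REFERENCE_INTENSITIES)


@pytest.fixture(scope="session")
def sim_panel():
    """A medium simulated cohort at the reference conditions, shared
    across tests that only read it."""
    return simulate_cohort(SimulationConfig(n_subjects=2000, seed=42))


def series_expm(Q, u, terms=60):
    """Independent truncated power-series oracle for the matrix
    exponential: sum (Qu)^k / k!."""
    A = np.asarray(Q, dtype=float) * u
    out = np.eye(A.shape[0])
    term = np.eye(A.shape[0])
    for k in range(1, terms + 1):
        term = term @ A / k
        out = out + term
    return out


@pytest.fixture(scope="session")
def printed_counts_panel():
    """Deterministic five-state panel reproducing the reference cohort's
    follow-up margins: 4051 subjects (3584 CF-free / 467 CF at
    baseline), 239 incident CF, 213 CF improvements, 61 CF deaths and
    286 CF-free deaths by year 4."""
    rows = []
    sid = 0

    def add(n, states_by_time):
        nonlocal sid
        for _ in range(n):
            sid += 1
            for t, s in states_by_time:
                rows.append((sid, float(t), s))

    # baseline CF-free: 1441 NS, 142 CI, 2001 PF = 3584
    add(239, [(0, 1), (2, 1), (4, 4)])          # incident CF (from NS)
    add(286, [(0, 3), (2, 5)])                  # CF-free deaths (from PF)
    add(1441 - 239, [(0, 1), (2, 1), (4, 1)])
    add(142, [(0, 2), (2, 2), (4, 2)])
    add(2001 - 286, [(0, 3), (2, 3), (4, 3)])
    # baseline CF: 213 improve, 61 die, rest stay
    add(213, [(0, 4), (2, 4), (4, 3)])
    add(61, [(0, 4), (2, 5)])
    add(467 - 213 - 61, [(0, 4), (2, 4), (4, 4)])
    df = pd.DataFrame(rows, columns=["subject_id", "time_years", "state"])
    return PanelDataset(df)
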