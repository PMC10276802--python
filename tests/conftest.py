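import numpy as np
import pytest

from kurasync import (
    CouplingSchedule,
    OscillatorEnsemble,
    SimulationConfig,
    simulate,
    table1_fixture,
)

# Reference study conditions: logistic coupling calibrated to cross the
# critical value near t = 1800 model-seconds, 2580-s horizon, zero phases.
PAPER_A = 0.0065
PAPER_C = 75.0
PAPER_K0 = 0.00718
PAPER_T_END = 2580.0


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture(scope="session")
def table1_ensemble(table1):
    return OscillatorEnsemble(table1.frequencies_hz)


@pytest.fixture(scope="session")
def paper_schedule():
    return CouplingSchedule.logistic(a=PAPER_A, C=PAPER_C, K0=PAPER_K0)


@pytest.fixture(scope="session")
def paper_run(table1_ensemble, paper_schedule):
    """The full reference run; integrated once and shared across tests."""
    config = SimulationConfig(t_end=PAPER_T_END, output_rate=1.0)
    return simulate(table1_ensemble, paper_schedule, config)


def dtw_bruteforce(x, y):
    """Minimum cost over ALL admissible warping paths, enumerated explicitly.

    Every monotone path from (0,0) to (n-1,m-1) with steps {(1,0), (0,1),
    (1,1)} is walked and costed: the (0,0) cell contributes |x_0 - y_0|
    once, and each subsequent step contributes the destination cell's local
    cost, doubled for diagonal steps.  Deliberately NOT the dynamic program
    (no recurrence, no memoization) so it is an independent oracle; only
    feasible for short sequences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    best = np.inf
    # stack of (i, j, cost so far)
    stack = [(0, 0, abs(x[0] - y[0]))]
    while stack:
        i, j, cost = stack.pop()
        if i == n - 1 and j == m - 1:
            best = min(best, cost)
            continue
        if i + 1 < n and j + 1 < m:
            stack.append((i + 1, j + 1, cost + 2.0 * abs(x[i + 1] - y[j + 1])))
        if i + 1 < n:
            stack.append((i + 1, j, cost + abs(x[i + 1] - y[j])))
        if j + 1 < m:
            stack.append((i, j + 1, cost + abs(x[i] - y[j + 1])))
    return best
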