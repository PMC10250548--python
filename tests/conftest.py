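import numpy as np
import pandas as pd
import pytest

from nascentquant.io_tables import QuantMatrix, _design_from_samples


def make_matrix(data: dict[str, list[float | None]], samples: list[str]) -> QuantMatrix:
    """QuantMatrix from row-id -> per-sample log2 values (None = missing)."""
    values = pd.DataFrame.from_dict(data, orient="index", columns=samples).astype(float)
    values.index.name = "protein"
    return QuantMatrix(values=values, design=_design_from_samples(samples))


@pytest.fixture
def nsp_fixture_matrix() -> QuantMatrix:
    """Six proteins, one per calling outcome, against 3+3 replicates.

    With background = {B1}: N1 -> NSP (absent-in-control), N2 -> NSP
    (enriched, log2FC = 5), B1 -> background, E1 -> identified-not-enriched
    (log2FC = 0.2 < log2 1.5), X1 -> not-identified (2/3 treated), X2 ->
    not-identified (control only).
    """
    samples = [f"treated_{i}" for i in (1, 2, 3)] + [f"control_{i}" for i in (1, 2, 3)]
    data = {
        "N1": [25.0, 25.1, 24.9, None, None, None],
        "N2": [25.0, 25.1, 24.9, 20.0, 20.1, 19.9],
        "B1": [22.0, 22.1, 21.9, 22.0, 22.1, 21.9],
        "E1": [22.0, 22.1, 21.9, 21.8, 21.9, 21.7],
        "X1": [24.0, 24.2, None, 20.0, 20.2, 20.1],
        "X2": [None, None, None, 23.0, 23.1, 22.9],
    }
    return make_matrix(data, samples)


@pytest.fixture
def timecourse_fixture_matrix() -> QuantMatrix:
    """Five proteins, one per presence-dynamics class, 2 reps x 4 windows.

    A: detected everywhere (steady only).  B: lost at 0-1h, regained at
    1-2h.  C: lost at 0-1h, never regained.  D: appears only after
    stimulation.  E: detected in a single replicate only (never detected
    under the all-replicates rule, so outside n_total).
    Hand counts: n_total = 4, n_steady = 3, n_lost = 2, n_regained = 1.
    """
    windows = ["steady", "0-1h", "1-2h", "3-4h"]
    samples = [f"tc@{w}_{r}" for w in windows for r in (1, 2)]
    V = 25.0
    data = {
        "A": [V, V, V, V, V, V, V, V],
        "B": [V, V, None, None, V, V, None, None],
        "C": [V, V, None, None, None, V, None, None],
        "D": [None, V, V, V, V, V, V, V],
        "E": [None, V, None, None, None, None, None, None],
    }
    return make_matrix(data, samples)
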