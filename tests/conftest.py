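import numpy as np
import pandas as pd
import pytest

from mirpair import SimParams, simulate_paired_counts


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-signal dataset shared by read-only tests."""
    params = SimParams(
        n_mirnas=200,
        frac_de=0.1,
        baseline_log2_mean_range=(5.0, 9.0),
        seed=123,
    )
    counts, sheet, truth = simulate_paired_counts(params)
    return counts, sheet, truth


@pytest.fixture()
def toy_sheet():
    """Minimal valid paired 2x2 sample sheet: 2 pairs per arm."""
    rows = []
    for cond, prefix in (("performance", "P"), ("control", "C")):
        for j in (1, 2):
            for time in ("pre", "post"):
                rows.append((f"{prefix}{j}_{time}", f"{prefix}{j}", cond, time))
    return pd.DataFrame(rows, columns=["sample_id", "pair_id", "condition", "time"])


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
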