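import numpy as np
import pandas as pd
import pytest

from biosimpk import (
    CovariateDistribution,
    PKDataset,
    TrialDesign,
    apply_exclusions,
    default_population,
    simulate_trial,
)


@pytest.fixture(scope="session")
def pop():
    """Bundled reference population parameters (simulation truth)."""
    return default_population()


@pytest.fixture(scope="session")
def small_trial(pop):
    """A 20-subject, 8-cycle simulated trial after exclusions."""
    design = TrialDesign(n_subjects=20, n_cycles=8, seed=101)
    ds = simulate_trial(design, CovariateDistribution(), pop)
    ds, _ = apply_exclusions(ds, design.lloq)
    return ds


def toy_dataset(rows):
    """Build a PKDataset from (ID, TIME, AMT, RATE, DV, EVID, extra) tuples."""
    recs = []
    for r in rows:
        rec = {
            "ID": r[0], "TIME": r[1], "NTIM": r[1], "AMT": r[2], "RATE": r[3],
            "DV": r[4], "EVID": r[5], "MDV": 0 if r[5] == 0 else 1,
            "BLQ": 0, "CYCLE": 1, "TAG": "", "BWT": 70.0, "SEX": 0, "PROD": 0,
        }
        rec.update(r[6] if len(r) > 6 else {})
        recs.append(rec)
    return PKDataset(pd.DataFrame(recs))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
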