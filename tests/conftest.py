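import io

import numpy as np
import pandas as pd
import pytest

from cqplan import CqDataset, SimulationSpec, simulate_stratum


@pytest.fixture
def balanced_stratum() -> CqDataset:
    """One simulated 4x4x3 stratum with realistic noise magnitudes."""
    return simulate_stratum(
        SimulationSpec(mu=24.0, sd_sampling=0.5, sd_rt=0.4, sd_qpcr=0.3, seed=42)
    )


@pytest.fixture
def unbalanced_stratum() -> CqDataset:
    """Tiny hand-enumerable unbalanced stratum: extractions with (2, 3) RTs,
    2 qPCR wells each (10 records)."""
    rng = np.random.default_rng(5)
    rows = []
    for i, n_rts in enumerate([2, 3], start=1):
        for j in range(1, n_rts + 1):
            for k in (1, 2):
                rows.append(("p1", "leaves", "g1", i, j, k,
                             24 + rng.normal(0, 0.6)))
    return CqDataset(pd.DataFrame(
        rows, columns=["subject", "tissue", "gene",
                       "rna_rep", "rt_rep", "qpcr_rep", "cq"]))


@pytest.fixture
def small_csv_text() -> str:
    return (
        "subject,tissue,gene,rna_rep,rt_rep,qpcr_rep,cq\n"
        "p1,leaves,VRN,1,1,1,24.10\n"
        "p1,leaves,VRN,1,1,2,24.35\n"
        "p1,leaves,VRN,1,2,1,23.90\n"
    )


@pytest.fixture
def csv_stream(small_csv_text):
    return io.StringIO(small_csv_text)
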