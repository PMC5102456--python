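import numpy as np
import pandas as pd
import pytest

from ihctyper.core_data import ScoreMatrix
from ihctyper.synthetic import CohortSpec, generate_cohort


def make_matrix(values, markers=None, diagnosis=None, probe=None):
    """Small hand-built ScoreMatrix; NaN = missing."""
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    markers = markers or [f"m{j+1}" for j in range(g)]
    sids = [f"s{i+1}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "patient_id": [f"p{i+1}" for i in range(n)],
            "diagnosis": diagnosis or ["pancreatic_ductal"] * n,
            "probe_type": probe or ["biopsy"] * n,
        },
        index=pd.Index(sids, name="sample_id"),
    )
    scores = pd.DataFrame(values, index=meta.index, columns=markers)
    return ScoreMatrix(scores, meta)


@pytest.fixture(scope="session")
def balanced_cohort():
    """Four-type cohort, 40 samples per type, 18% panel-block missingness."""
    spec = CohortSpec(
        n_per_type={t: 40 for t in ("EPB", "INT", "ICC", "HCC")},
        missing_rate=0.18,
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def complete_cohort():
    """Same four-type cohort without any missingness."""
    spec = CohortSpec(
        n_per_type={t: 40 for t in ("EPB", "INT", "ICC", "HCC")},
        missing_rate=0.0,
        seed=11,
    )
    return generate_cohort(spec)
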