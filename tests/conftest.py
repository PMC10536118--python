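import numpy as np
import pandas as pd
import pytest

from rilimet import SampleTable, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort, seed 7 (session-scoped: read-only)."""
    return simulate_cohort(SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """Cheap cohort for I/O and plumbing tests."""
    cfg = SimConfig(seed=3, n_metabolites=30, n_planted_markers=6,
                    qc_n=4, missing_rate=0.1)
    return simulate_cohort(cfg)


def make_table(abund, tissue="plasma", dose=None, day=5.0, role=None,
               weight=None, chem_class=None, acyl_chain=None,
               is_channel=None, normalized="raw"):
    """Hand-build a SampleTable from a dict/DataFrame of abundances."""
    ab = pd.DataFrame(abund, dtype=float)
    n = len(ab)
    sm = pd.DataFrame({
        "animal_id": [f"A{i}" for i in range(n)],
        "tissue": tissue,
        "dose_gy": dose if dose is not None else [0.0] * n,
        "day": day,
        "role": role if role is not None else ["study"] * n,
        "tissue_weight_mg": weight if weight is not None
        else ([20.0] * n if tissue == "lung" else [np.nan] * n),
    }, index=ab.index)
    mm = pd.DataFrame({
        "name": list(ab.columns),
        "chem_class": chem_class if chem_class is not None
        else ["other"] * ab.shape[1],
        "acyl_chain": acyl_chain if acyl_chain is not None
        else [None] * ab.shape[1],
        "is_channel": is_channel if is_channel is not None
        else [None] * ab.shape[1],
    }, index=ab.columns)
    return SampleTable(ab, sm, mm, normalized=normalized)
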