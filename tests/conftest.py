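import numpy as np
import pandas as pd
import pytest

from oralmicro.io_model import CountMatrix, SampleFrame
from oralmicro.synthetic_cohort import SimConfig, simulate_cohort


def make_sample_frame(groups, **overrides) -> SampleFrame:
    """Minimal valid SampleFrame for a list of group labels."""
    n = len(groups)
    data = {
        "sample_id": [f"s{i}" for i in range(n)],
        "group": list(groups),
        "age": 15.0,
        "sex": 0,
        "race_white": 0,
        "ethnicity_hispanic": 0,
        "dental_visit_past_year": 0,
        "antibiotic_past_3mo": 0,
        "periodontitis": 0,
        "caries": 0,
        "total_reads": 1000,
    }
    data.update(overrides)
    return SampleFrame(pd.DataFrame(data))


def make_count_matrix(counts, sample_ids=None, genus=None, species=None) -> CountMatrix:
    arr = np.asarray(counts, dtype=np.int64)
    n_taxa, n_samples = arr.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n_samples)]
    taxon_ids = pd.Index([f"t{j}" for j in range(n_taxa)], name="taxon_id")
    tax = pd.DataFrame({
        "genus": genus if genus is not None else [f"g{j}" for j in range(n_taxa)],
        "species": species if species is not None else [f"sp{j}" for j in range(n_taxa)],
    }, index=taxon_ids)
    return CountMatrix(pd.DataFrame(arr, index=taxon_ids, columns=sample_ids), tax)


@pytest.fixture(scope="session")
def small_cohort():
    """A 254-sample, 40-taxon cohort with two planted depletions."""
    log_rr = np.zeros(40)
    log_rr[0] = np.log(0.2)
    log_rr[1] = np.log(0.25)
    cfg = SimConfig(n_taxa=40, baseline_log_mean=np.zeros(40),
                    dispersion=np.ones(40), group_log_rr=log_rr, seed=11)
    return simulate_cohort(cfg)
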