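import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from oligohox import synthetic as syn


@pytest.fixture(scope="session")
def bulk_cohort():
    """Mid-sized bulk cohort with planted truth (shared across tests)."""
    truth = syn.BulkCohortTruth(n=500, seed=11)
    clinical, meth, expr = syn.gen_bulk_cohort(truth)
    return truth, clinical, meth, expr


@pytest.fixture(scope="session")
def sn_dataset():
    """Single-nucleus dataset with planted 1p/19q loss and cell states."""
    truth = syn.SnTruth(n_nuclei=1500, genes_per_arm=150, seed=7)
    counts, features, barcodes, annotation = syn.gen_snseq(truth)
    return truth, counts, features, barcodes, annotation
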