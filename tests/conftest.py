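import numpy as np
import pytest

from mirmeta import io
from mirmeta.datatypes import ArmSummary


@pytest.fixture(scope="session")
def meta_rows():
    """Study rows of the packaged miR-17 gastric-cancer meta-analysis table."""
    return io.study_rows_from_frame(io.load_case_study("meta_studies"))


@pytest.fixture(scope="session")
def tissue_rows(meta_rows):
    return [r for r in meta_rows if r.sample_type == "tissue"]


@pytest.fixture(scope="session")
def serum_rows(meta_rows):
    return [r for r in meta_rows if r.sample_type in ("serum", "blood")]


@pytest.fixture(scope="session")
def clinical_table():
    return io.load_case_study("clinical_summaries")


@pytest.fixture(scope="session")
def clinical_arms(clinical_table):
    """characteristic -> ordered list of ArmSummary rows."""
    out = {}
    for char, sub in clinical_table.groupby("characteristic", sort=False):
        out[char] = [
            ArmSummary(int(r.n), float(r.mean), float(r.sd)) for r in sub.itertuples()
        ]
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
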