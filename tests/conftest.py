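import numpy as np
import pandas as pd
import pytest

import linkqa
from linkqa import synthetic_data as sd


@pytest.fixture
def small_population():
    spec = sd.PopulationSpec(n_persons=200, twin_rate=0.0)
    return linkqa.generate_population(spec, seed=42)


@pytest.fixture
def clean_files(small_population):
    """Two uncorrupted derivations of the same population."""
    corr = sd.CorruptionSpec()
    fa, tma = sd.derive_file(small_population, corr, seed=1, file_id="a")
    fb, tmb = sd.derive_file(small_population, corr, seed=2, file_id="b")
    return fa, fb


@pytest.fixture
def noisy_files(small_population):
    corr = linkqa.uniform_corruption(typo=0.05, missing=0.05, update_postcode=0.1)
    fa, _ = sd.derive_file(small_population, corr, seed=3, file_id="a")
    fb, _ = sd.derive_file(small_population, corr, seed=4, file_id="b")
    return fa, fb


@pytest.fixture
def csv_records(tmp_path):
    """A small raw CSV with messy case/whitespace and a missing cell."""
    path = tmp_path / "records.csv"
    path.write_text(
        "id,surname,dob,sex\n"
        "r1,  smith ,1980-01-02,M\n"
        "r2,Jones  Brown,,F\n"
        "r3,o'neill,1999-12-31,M\n"
    )
    return path
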