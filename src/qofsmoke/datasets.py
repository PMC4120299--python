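"""Small reference tables shipped with the package.

Both tables transcribe published 2012/13 values: a five-practice worked
example of the indicator extract, and the per-district reference of
census population, register-covered population, practice counts and
survey sample sizes for the 16 study districts.
"""

from __future__ import annotations

from importlib import resources
from typing import List

import pandas as pd

from .qof_io import DEFAULT_CODE_MAP, read_indicator_table
from .types import PracticeIndicatorRecord


def _data_path(name: str):
    return resources.files("qofsmoke.data").joinpath(name)


def load_example_indicator_records() -> List[PracticeIndicatorRecord]:
    """Five worked-example practices (A-E) for 2012/13, as validated records."""
    with resources.as_file(_data_path("example_practices_2012_13.csv")) as p:
        return read_indicator_table(p, DEFAULT_CODE_MAP)


def load_district_reference() -> pd.DataFrame:
    """Per-district reference table for the 16 study districts (2012/13).

    Columns: district_code, county, census_population_15plus,
    qof_sm07_population, n_practices, ihs_sample_size.
    """
    with resources.as_file(_data_path("district_reference_2012_13.csv")) as p:
        return pd.read_csv(p)
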