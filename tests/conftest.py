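import pandas as pd
import pytest

import pointscore as ps


@pytest.fixture
def tiny_csv(tmp_path):
    """4-row mixed-type cohort file."""
    p = tmp_path / "cohort.csv"
    p.write_text(
        "age,sex,death\n"
        "63,male,0\n"
        "71,female,1\n"
        "45,male,0\n"
        "80,female,0\n"
    )
    return p


@pytest.fixture
def tiny_schema():
    return {"age": "continuous", "sex": "categorical"}


@pytest.fixture(scope="session")
def small_cohort():
    """Generic 3-signal/2-noise cohort used by several module tests."""
    spec = ps.simple_spec(n=2000, n_signal=3, n_noise=2, seed=7)
    return ps.generate_cohort(spec)


@pytest.fixture(scope="session")
def ehr_cohort():
    """Default EHR-like cohort at a size small enough for unit tests."""
    spec = ps.default_ehr_spec(n=6000, seed=3)
    return ps.generate_cohort(spec)


def make_cohort(df: pd.DataFrame, outcome: str = "death", **kinds) -> ps.CohortTable:
    if not kinds:
        kinds = {
            c: ("continuous" if pd.api.types.is_numeric_dtype(df[c]) else "categorical")
            for c in df.columns
            if c != outcome
        }
    return ps.CohortTable(data=df, outcome=outcome, var_kinds=kinds)
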