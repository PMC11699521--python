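import numpy as np
import pandas as pd
import pytest

from screenscore.cohort import (
    Cohort,
    GeneratorConfig,
    attach_pack_years,
    attach_spirometry,
    make_retest,
    sample_cohort,
)
from screenscore.schema import (
    QuestionItem,
    QuestionnaireSchema,
    load_schema,
    table2_distributions,
)


@pytest.fixture(scope="session")
def schema():
    return load_schema("copd_eq_v1")


@pytest.fixture(scope="session")
def dists(schema):
    return table2_distributions(schema)


@pytest.fixture(scope="session")
def cohort_full(schema, dists):
    """Development-cohort-sized synthetic cohort with all attachments."""
    c = sample_cohort(dists, GeneratorConfig(n_case=404, n_control=1420, seed=7))
    c = attach_pack_years(c, seed=8)
    c = attach_spirometry(c, seed=9)
    c = make_retest(c, agreement=0.9, seed=10)
    return c


@pytest.fixture(scope="session")
def cohort_small(schema, dists):
    c = sample_cohort(dists, GeneratorConfig(n_case=120, n_control=380, seed=3))
    return attach_pack_years(c, seed=4)


def make_toy_cohort(
    rng: np.random.Generator,
    choice_counts=(3, 2, 4),
    n: int = 200,
    signal: float = 0.2,
) -> Cohort:
    """Small random cohort over a toy schema; class odds increase with item codes."""
    items = tuple(
        QuestionItem(f"it{i}", f"toy question {i}", tuple(str(j) for j in range(k)))
        for i, k in enumerate(choice_counts)
    )
    sch = QuestionnaireSchema(items, version="toy")
    df = pd.DataFrame({it.id: rng.integers(0, it.n_choices, n) for it in sch})
    severity = sum(df[it.id] / (it.n_choices - 1) for it in sch) / len(items)
    p = 0.25 + signal * severity
    df["label"] = np.where(rng.random(n) < p, "case", "control")
    if (df["label"] == "case").sum() == 0:
        df.loc[0, "label"] = "case"
    if (df["label"] == "control").sum() == 0:
        df.loc[1, "label"] = "control"
    df.insert(0, "subject_id", [f"t{i}" for i in range(n)])
    return Cohort(sch, df)
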