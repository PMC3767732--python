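import numpy as np
import pandas as pd
import pytest

from lobeconcord.io_formats import ExpressionMatrix, SampleAnnotation
from lobeconcord.synthetic import SyntheticConfig, generate_cohort


def make_expr(values, probes=None, samples=None, scale="linear"):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=probes, columns=samples), scale=scale)


def make_ann(rows):
    """rows: iterable of (sample_id, subject_id, site, group)."""
    df = pd.DataFrame(rows, columns=["sample_id", "subject_id", "site", "group"])
    return SampleAnnotation(df.set_index("sample_id"))


def paired_ann(n_subjects, prefix="S", group="smoker"):
    rows = []
    for i in range(n_subjects):
        subj = f"{prefix}{i}"
        rows.append((f"{subj}_u", subj, "upper", group))
        rows.append((f"{subj}_l", subj, "lower", group))
    return make_ann(rows)


@pytest.fixture(scope="session")
def small_cohort():
    """Fast cohort used across modules: 5 paired smokers, 12 nonsmokers,
    400 probes with 60 planted responsive ones."""
    cfg = SyntheticConfig(
        n_subjects=5, n_nonsmokers=12, m_total=400, m_sig=60, n_absent=20, seed=11
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The generator's default study conditions (11 paired smokers,
    60 nonsmokers, 5000 probes, 529 responsive), seed 0."""
    return generate_cohort(SyntheticConfig(seed=0))
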