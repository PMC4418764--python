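import numpy as np
import pandas as pd
import pytest

from mirkey.diffexpr import DifferentialCallSet, ExpressionMatrix
from mirkey.synthetic_data import load_table_fixture


@pytest.fixture(scope="session")
def table1():
    return load_table_fixture("T1")


@pytest.fixture(scope="session")
def table2():
    return load_table_fixture("T2")


@pytest.fixture(scope="session")
def table3():
    return load_table_fixture("T3")


@pytest.fixture(scope="session")
def table1_callset(table1):
    return DifferentialCallSet(
        calls={
            grade: (frozenset(up), frozenset(down))
            for grade, (up, down) in table1.grade_lists().items()
        },
        threshold_fold=2.0,
    )


def make_matrix(intensities: np.ndarray, grades=("GI",), mirna_ids=None) -> ExpressionMatrix:
    """Build an ExpressionMatrix from an array of shape (n_mirnas, 2 * n_pairs).

    Columns alternate tumor, normal per patient; patients are spread evenly
    over ``grades``.
    """
    n_mirnas, n_cols = intensities.shape
    assert n_cols % 2 == 0
    n_pairs = n_cols // 2
    if mirna_ids is None:
        mirna_ids = [f"m{i}" for i in range(n_mirnas)]
    columns, rows = [], []
    for p in range(n_pairs):
        grade = grades[p % len(grades)]
        patient = f"{grade}-P{p}"
        columns += [f"{patient}-T", f"{patient}-N"]
        rows.append((f"{patient}-T", patient, grade, "tumor"))
        rows.append((f"{patient}-N", patient, grade, "normal"))
    expr = pd.DataFrame(intensities, index=mirna_ids, columns=columns)
    samples = pd.DataFrame(
        rows, columns=["sample_id", "patient_id", "grade", "tissue"]
    ).set_index("sample_id")
    return ExpressionMatrix(intensities=expr, samples=samples)
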