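import numpy as np
import pandas as pd
import pytest

from rfepp.io_tables import ExpressionMatrix


def make_matrix(values, sample_ids=None, feature_ids=None, classes=None):
    """Small helper: build an ExpressionMatrix from a nested list (None=missing)."""
    values = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in values]
    )
    n, k = values.shape
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(n)]
    feature_ids = feature_ids or [f"f{j + 1}" for j in range(k)]
    data = pd.DataFrame(values, index=pd.Index(sample_ids, name="files"),
                        columns=feature_ids)
    cls = None
    if classes is not None:
        cls = pd.Series(list(classes), index=data.index, dtype=str)
    return ExpressionMatrix(data, cls)


@pytest.fixture
def two_class_matrix():
    """12 samples x 4 features, two classes, one missing cell per class."""
    rng = np.random.default_rng(7)
    values = rng.normal(10, 2, size=(12, 4))
    m = make_matrix(values, classes=["A"] * 6 + ["B"] * 6)
    m.data.iloc[1, 2] = np.nan
    m.data.iloc[8, 0] = np.nan
    return m


@pytest.fixture
def separable_matrix():
    """Two classes perfectly separated by feature 'sig'; 3 noise features."""
    rng = np.random.default_rng(11)
    n = 20
    sig = np.array([0.0] * (n // 2) + [10.0] * (n // 2))
    noise = rng.standard_normal((n, 3))
    values = np.column_stack([sig, noise])
    return make_matrix(values, feature_ids=["sig", "n1", "n2", "n3"],
                       classes=["A"] * (n // 2) + ["B"] * (n // 2))


@pytest.fixture
def demo_expression_csv(tmp_path):
    """Demo-scale expression table CSV: 24 samples, 12 features, 2 classes."""
    rng = np.random.default_rng(3)
    n, k = 24, 12
    base = rng.normal(12, 1.5, size=(n, k))
    labels = ["HD"] * 12 + ["MF"] * 12
    base[12:, 0] += 4.0  # one genuinely discriminating feature
    base[12:, 1] += 2.5
    rows = ["files," + ",".join(f"prot_{j}" for j in range(k)) + ",class"]
    for i in range(n):
        cells = [f"{v:.4f}" for v in base[i]]
        if i % 7 == 3:
            cells[5] = ""  # scatter a few missing values
        rows.append(f"sample_{i}.raw," + ",".join(cells) + f",{labels[i]}")
    path = tmp_path / "expression.csv"
    path.write_text("\n".join(rows) + "\n")
    return path
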