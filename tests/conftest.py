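import numpy as np
import pandas as pd
import pytest

import immucerna as ic


@pytest.fixture(scope="session")
def default_sim() -> ic.TranscriptomeSimulation:
    """One default synthetic cohort shared by read-only tests."""
    return ic.simulate_transcriptome(seed=11)


@pytest.fixture()
def tiny_expr() -> ic.ExpressionMatrix:
    """4 genes x 6 samples, hand-constructed, log2 scale."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 5.0, 3.0],
            "s2": [2.0, 1.0, 5.0, 3.0],
            "s3": [3.0, 4.0, 5.0, 3.0],
            "s4": [4.0, 3.0, 5.0, 7.0],
            "s5": [5.0, 6.0, 5.0, 7.0],
            "s6": [6.0, 5.0, 5.0, 7.0],
        },
        index=["gA", "gB", "gC", "gD"],
    )
    groups = {f"s{i}": "control" if i <= 3 else "case" for i in range(1, 7)}
    return ic.ExpressionMatrix(values=values, groups=groups, scale="log2")


@pytest.fixture()
def toy_catalog() -> ic.GeneCatalog:
    table = pd.DataFrame(
        {
            "biotype": ["mRNA", "lncRNA", "mRNA", "lncRNA", "mRNA"],
            "is_immune": [True, False, False, False, True],
        },
        index=["RABEP1", "JPX", "ACTB", "MALAT1", "TBK1"],
    )
    return ic.GeneCatalog(table=table)


def pooled_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Brute-force product-moment correlation, independent of the package."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))
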