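import numpy as np
import pandas as pd
import pytest

from mirhinge import ExpressionMatrix, InteractionTable


@pytest.fixture
def small_genes() -> ExpressionMatrix:
    rng = np.random.default_rng(7)
    df = pd.DataFrame(rng.normal(size=(4, 12)),
                      index=[f"g{i}" for i in range(4)],
                      columns=[f"s{i}" for i in range(12)])
    return ExpressionMatrix(df, kind="gene", unit="arbitrary")


@pytest.fixture
def small_mirnas() -> ExpressionMatrix:
    rng = np.random.default_rng(8)
    df = pd.DataFrame(rng.normal(size=(3, 12)),
                      index=[f"m{i}" for i in range(3)],
                      columns=[f"s{i}" for i in range(12)])
    return ExpressionMatrix(df, kind="miRNA", unit="arbitrary")


@pytest.fixture
def small_pairs() -> InteractionTable:
    rows = [(m, g) for m in ("m0", "m1", "m2") for g in ("g0", "g1", "g2", "g3")]
    return InteractionTable(pd.DataFrame(rows, columns=["mirna", "gene"]))
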