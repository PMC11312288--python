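from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from microsig import ExpressionMatrix, SignatureSet


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240730)


@pytest.fixture
def toy_expression() -> ExpressionMatrix:
    """Two genes, 3 vs 3 samples: one flat gene, one with a clean shift."""
    values = pd.DataFrame(
        {
            "WT_1": [1.0, 5.0],
            "WT_2": [2.0, 5.1],
            "WT_3": [3.0, 4.9],
            "KO_1": [4.0, 5.0],
            "KO_2": [5.0, 5.1],
            "KO_3": [6.0, 4.9],
        },
        index=["Shift", "Flat"],
    )
    cond = {s: s.split("_")[0] for s in values.columns}
    return ExpressionMatrix(values=values, condition=cond)


def random_signature_set(rng: np.random.Generator, n: int = 6, n_genes: int = 50) -> SignatureSet:
    values = pd.DataFrame(
        rng.normal(size=(n, n_genes)),
        index=[f"P{i}" for i in range(n)],
        columns=[f"g{i}" for i in range(n_genes)],
    )
    return SignatureSet(values=values)
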