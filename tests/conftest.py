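import numpy as np
import pandas as pd
import pytest

from matriscope.io import ExpressionMatrix, MatrisomeCatalog, SampleTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_counts():
    """A 6-gene x 4-sample count matrix with no zero rows."""
    data = pd.DataFrame(
        [
            [10, 20, 15, 12],
            [100, 180, 160, 110],
            [5, 9, 7, 6],
            [40, 85, 70, 45],
            [7, 13, 11, 8],
            [250, 480, 420, 260],
        ],
        index=[f"ENSG{i:011d}" for i in range(6)],
        columns=[f"S{j}" for j in range(4)],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def tiny_catalog():
    genes = [f"ENSG{i:011d}" for i in range(10)]
    cats = [
        "collagens",
        "collagens",
        "proteoglycans",
        "ECM_glycoproteins",
        "ECM_glycoproteins",
        "ECM_regulators",
        "ECM_regulators",
        "ECM_affiliated",
        "secreted_factors",
        "secreted_factors",
    ]
    table = pd.DataFrame(
        {
            "division": [
                "core" if c in ("collagens", "proteoglycans", "ECM_glycoproteins") else "associated"
                for c in cats
            ],
            "category": cats,
        },
        index=pd.Index(genes, name="gene"),
    )
    return MatrisomeCatalog(table)


def make_sample_table(sample_ids, tissues, **extra):
    frame = pd.DataFrame(
        {
            "subject_id": extra.get("subject_id", [f"SUBJ{i}" for i in range(len(sample_ids))]),
            "tissue": tissues,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    for key, values in extra.items():
        if key != "subject_id":
            frame[key] = values
    return SampleTable(frame)
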