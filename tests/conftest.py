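import numpy as np
import pytest

from isenics import ExpressionMatrix, GeneList, SignedGeneSet


@pytest.fixture
def small_matrix():
    """5 genes x 4 units with fixed, hand-readable TPM values."""
    values = np.array(
        [
            [1.0, 8.0, 3.0, 0.5],
            [7.0, 2.0, 9.0, 4.0],
            [0.0, 5.0, 1.0, 6.0],
            [3.0, 3.0, 2.0, 8.0],
            [9.0, 1.0, 4.0, 2.0],
        ]
    )
    return ExpressionMatrix(
        gene_ids=["G1", "G2", "G3", "G4", "G5"],
        unit_ids=["u1", "u2", "u3", "u4"],
        values=values,
        scale="tpm",
    )


@pytest.fixture
def signed_set():
    return SignedGeneSet("SIG", positive={"G1", "G2"}, negative={"G4", "G5"})


def random_matrix(rng, n_genes, n_units, scale="tpm"):
    values = np.round(rng.gamma(2.0, 3.0, size=(n_genes, n_units)), 3)
    return ExpressionMatrix(
        gene_ids=[f"G{i}" for i in range(n_genes)],
        unit_ids=[f"u{j}" for j in range(n_units)],
        values=values,
        scale=scale,
    )


@pytest.fixture
def gene_universe():
    return GeneList("universe", {f"GENE{i}" for i in range(30)})
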