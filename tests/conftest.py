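import numpy as np
import pandas as pd
import pytest

from mucopep.io import AMINO_ACIDS, AbundanceTable, LabeledPeptideSet, Peptide


def random_peptide(rng: np.random.Generator, pid: str, lo: int = 5, hi: int = 30) -> Peptide:
    length = int(rng.integers(lo, hi + 1))
    seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))
    return Peptide(pid, seq)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def random_peptides(rng):
    return [random_peptide(rng, f"pep{i:03d}") for i in range(50)]


@pytest.fixture
def small_abundance() -> AbundanceTable:
    """3 peptides x 2 species x 2 replicates with one undetected cell pair."""
    cols = pd.MultiIndex.from_product(
        [["spA", "spB"], ["r1", "r2"]], names=["species", "replicate"]
    )
    data = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],  # present everywhere
            [0.0, 5.2, 0.0, 0.0],  # present in spA only
            [0.0, 0.0, 2.0, 1.0],  # present in spB only
        ]
    )
    return AbundanceTable(pd.DataFrame(data, index=["p1", "p2", "p3"], columns=cols))


def labeled_set(rng: np.random.Generator, n_pos: int, n_neg: int,
                name: str = "test-property") -> LabeledPeptideSet:
    peptides = [random_peptide(rng, f"pos{i}") for i in range(n_pos)] + [
        random_peptide(rng, f"neg{i}") for i in range(n_neg)
    ]
    labels = np.r_[np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)]
    return LabeledPeptideSet(name, peptides, labels)
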