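import numpy as np
import pytest

from alignstat.seqio import Alignment, SequenceRecord


def make_alignment(*pairs: tuple[str, str]) -> Alignment:
    return Alignment([SequenceRecord(id=i, residues=s) for i, s in pairs])


def random_alignment(rng: np.random.Generator, n: int, width: int,
                     gap_frac: float = 0.05, n_frac: float = 0.02) -> Alignment:
    chars = np.array(list("ACGT"))
    mat = rng.choice(chars, size=(n, width))
    mat[rng.random(mat.shape) < gap_frac] = "-"
    mat[rng.random(mat.shape) < n_frac] = "N"
    recs = [SequenceRecord(id=f"r{i}", residues="".join(row))
            for i, row in enumerate(mat)]
    return Alignment(recs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_alignment():
    # 4 sequences x 8 columns: SNPs at columns 3 (A/G) and 6 (C/T),
    # a gap column at 8
    return make_alignment(
        ("a", "ACATGCAA"),
        ("b", "ACATGCAA"),
        ("c", "ACGTGTAA"),
        ("d", "ACGTGTA-"),
    )
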