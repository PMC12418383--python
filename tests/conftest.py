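import numpy as np
import pytest

from utr5xpress.io_dataset import Dataset, UTRRecord


@pytest.fixture
def toy_dataset() -> Dataset:
    return Dataset(
        [
            UTRRecord("u1", "ACGTACGTACGT", te_value=1.5, rpkm=50.0, cell_line="PC3"),
            UTRRecord("u2", "GGGGAAAACCCC", te_value=-0.5, rpkm=20.0, cell_line="PC3"),
            UTRRecord("u3", "ATATATATATAT", te_value=0.2, rpkm=15.0, cell_line="HEK293T"),
        ]
    )


@pytest.fixture
def toy_fasta(tmp_path):
    path = tmp_path / "toy.fasta"
    path.write_text(">u1 some description\nACGTACGT\nACGT\n>u2\nggggaaaacccc\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
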