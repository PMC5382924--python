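import numpy as np
import pytest

from crisprleader.simulate import SimConfig, generate_synthetic_dataset

DNA = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(DNA[i] for i in rng.integers(4, size=n))


@pytest.fixture(scope="session")
def default_dataset():
    """The default clean synthetic dataset (30 loci, all rates zero)."""
    config = SimConfig(seed=0)
    records, truth = generate_synthetic_dataset(config)
    return config, records, truth


@pytest.fixture(scope="session")
def small_dataset():
    """A smaller clean dataset for faster end-to-end tests."""
    config = SimConfig(n_loci=12, seed=3)
    records, truth = generate_synthetic_dataset(config)
    return config, records, truth


GENBANK_TEXT = """\
LOCUS       TESTREC                   40 bp    DNA     linear   BCT 01-JAN-2000
DEFINITION  synthetic test record.
ACCESSION   TESTREC
VERSION     TESTREC.1
FEATURES             Location/Qualifiers
     CDS             10..18
                     /product="csn2"
                     /translation="MKL"
     CDS             complement(20..28)
                     /product="cas9"
ORIGIN
        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
//
"""


@pytest.fixture()
def genbank_file(tmp_path):
    path = tmp_path / "test.gbk"
    path.write_text(GENBANK_TEXT)
    return path
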