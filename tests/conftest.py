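import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hidtree import GenotypeMatrix

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


SPEC_MATRIX_TEXT = (
    "MarkerID\tHM001\tHM002\tHM003\n"
    "mk1\t0/0\t1/1\t0/1\n"
    "mk2\t./.\t0/0\t1/1\n"
)


@pytest.fixture
def spec_matrix_text() -> str:
    """2-marker x 3-accession fixture covering all four token kinds."""
    return SPEC_MATRIX_TEXT


def make_matrix(rows: dict[str, list[str]], accessions: list[str]) -> GenotypeMatrix:
    tokens = np.array([rows[m] for m in rows], dtype=object)
    return GenotypeMatrix(list(rows), accessions, tokens)


@pytest.fixture
def make_matrix_fn():
    return make_matrix


TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4\tS5
chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/0\t1/1\t1/1\t0/1
chr1\t200\t.\tATTTTT\tA\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0\t1/1\t1/1
chr1\t300\t.\tGCC\tG\t.\tPASS\t.\tGT\t./.\t./.\t./.\t0/0\t1/1
chr1\t400\t.\tTACGTACGTACGT\tT\t.\tPASS\t.\tGT\t0/0\t1/1\t0/0\t1/1\t0/0
chr1\t500\t.\tCAA\tC,CAAAA\t.\tPASS\t.\tGT\t0/0\t1/1\t2/2\t0/0\t1/1
chr1\t600\t.\tGTT\tG\t.\tPASS\t.\tGT\t0/1\t0/1\t0/1\t0/0\t1/1
"""


@pytest.fixture
def toy_vcf(tmp_path):
    """Six-record VCF over 5 samples: a SNP, a clean 5-bp deletion, a 60%%-
    missing 2-bp deletion, a clean 12-bp deletion, a multi-allelic INDEL and
    a 60%%-het 2-bp deletion."""
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path
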