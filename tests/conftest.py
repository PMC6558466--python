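import numpy as np
import pytest
from hypothesis import settings

from grskit import SNPCatalog, SNPRecord

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def single_snp_catalog():
    """One SNP with f=0.3, OR=1.2 — every closed form is hand-checkable."""
    return SNPCatalog("toy", (SNPRecord("rs1", "1", 100, "A", "G", 1.2, 0.3),))


@pytest.fixture
def small_catalog():
    return SNPCatalog(
        "toy",
        (
            SNPRecord("rs1", "1", 100, "A", "G", 1.2, 0.3),
            SNPRecord("rs2", "2", 200, "C", "T", 1.35, 0.5),
            SNPRecord("rs3", "3", 300, "G", "A", 0.9, 0.12),
        ),
    )


@pytest.fixture
def catalog_tsv(tmp_path, small_catalog):
    from grskit import write_catalog

    path = tmp_path / "catalog.tsv"
    write_catalog(small_catalog, path)
    return path


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##contig=<ID=2>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
"""

# Three subjects; sites chosen to exercise every orientation case:
#   rs_alt   risk=ALT             -> unchanged
#   rs_ref   risk=REF             -> reflected
#   rs_flip  risk on other strand -> complement then reflected
#   rs_ambig A/T, direct match    -> aligned without complement
#   rs_miss  has a ./. genotype
VCF_BODY = """\
1\t100\trs_alt\tG\tA\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0
1\t200\trs_ref\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0
1\t300\trs_flip\tT\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
2\t400\trs_ambig\tA\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t0/1
2\t500\trs_miss\tC\tG\t.\tPASS\t.\tGT\t./.\t0/1\t1/1
"""


@pytest.fixture
def vcf_path(tmp_path):
    path = tmp_path / "cohort.vcf"
    path.write_text(VCF_HEADER + VCF_BODY)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
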