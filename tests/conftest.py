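import numpy as np
import pytest

from phasebeam.panel import HaplotypePanel
from phasebeam.reconcile import MatchClass, TargetRefAlignment


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_panel(rng, n_haps, n_sites):
    return HaplotypePanel(rng.integers(0, 2, size=(n_haps, n_sites)))


def identity_alignment(n_sites):
    """Alignment where every target site maps 1:1 to the same reference site."""
    return TargetRefAlignment(
        [MatchClass.SHARED] * n_sites,
        np.arange(n_sites),
        np.zeros(n_sites, dtype=bool),
    )


REF_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
1\t100\trs1\tA\tC\t.\tPASS\t.\tGT\t0|1\t1|1
1\t200\trs2\tG\tT\t.\tPASS\t.\tGT\t0|0\t0|1
1\t300\trs3\tT\tA\t.\tPASS\t.\tGT\t1|0\t0|0
"""


@pytest.fixture
def tiny_ref_vcf(tmp_path):
    p = tmp_path / "ref.vcf"
    p.write_text(REF_VCF)
    return p
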