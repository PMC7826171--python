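import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small emitted dataset shared by pipeline-level tests."""
    from balscan.simulate import SimConfig, emit_dataset

    config = SimConfig(seed=5, n_neutral_loci=5, n_balanced_loci=2)
    outdir = tmp_path_factory.mktemp("dataset")
    paths = emit_dataset(config, outdir)
    return config, paths


GFF_TEXT = """##gff-version 3
chr1\ttest\tgene\t100\t400\t.\t+\t.\tID=gplus
chr1\ttest\tmRNA\t100\t400\t.\t+\t.\tID=gplus.t1;Parent=gplus
chr1\ttest\texon\t100\t400\t.\t+\t.\tParent=gplus.t1
chr1\ttest\tCDS\t150\t350\t.\t+\t0\tParent=gplus.t1
chr1\ttest\tgene\t1100\t1400\t.\t-\t.\tID=gminus
chr1\ttest\tmRNA\t1100\t1400\t.\t-\t.\tID=gminus.t1;Parent=gminus
chr1\ttest\texon\t1100\t1400\t.\t-\t.\tParent=gminus.t1
chr1\ttest\tCDS\t1150\t1350\t.\t-\t0\tParent=gminus.t1
chr1\ttest\tgene\t2000\t2099\t.\t+\t.\tID=gbadframe
chr1\ttest\tmRNA\t2000\t2099\t.\t+\t.\tID=gbadframe.t1;Parent=gbadframe
chr1\ttest\texon\t2000\t2099\t.\t+\t.\tParent=gbadframe.t1
chr1\ttest\tCDS\t2000\t2099\t.\t+\t0\tParent=gbadframe.t1
"""


@pytest.fixture()
def gff_file(tmp_path):
    p = tmp_path / "models.gff3"
    p.write_text(GFF_TEXT)
    return p


VCF_TEXT = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=5000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tind1\tind2\tog
chr1\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t1|1\t0/1
chr1\t20\t.\tC\tG\t.\tPASS\t.\tGT\t0/1\t0|0\t1|1
chr1\t30\t.\tG\tA\t.\tPASS\t.\tGT\t1|0\t0/0\t./.
"""


@pytest.fixture()
def vcf_file(tmp_path):
    p = tmp_path / "phased.vcf"
    p.write_text(VCF_TEXT)
    return p


@pytest.fixture()
def vcf_manifest():
    return {
        "ind1": ("P1", "focal"),
        "ind2": ("P2", "focal"),
        "og": ("OUT", "outgroup"),
    }
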