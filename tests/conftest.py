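import numpy as np
import pytest
from hypothesis import settings

from sorascan.synthetic import DiscoveryDesign, make_discovery_cohort

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def discovery_cohort(tmp_path_factory):
    """One generated discovery cohort (study-default design, fixed seed)."""
    out = tmp_path_factory.mktemp("discovery")
    return make_discovery_cohort(DiscoveryDesign(seed=7), out)


@pytest.fixture
def rng():
    return np.random.default_rng(20230415)


def write_vcf_text(path, body, samples=("S1", "S2", "S3")):
    """Write a minimal VCF from raw record lines (helper for parser tests)."""
    header = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
        + "\n"
    )
    path.write_text(header + body)
    return path
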