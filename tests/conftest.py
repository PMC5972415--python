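import numpy as np
import pytest

from gusld.model import d_bounds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_valid_params(rng, eps_choices=(0.0, 0.001, 0.01, 0.1), margin=0.9):
    """Random (p1, p2, D, eps) with D strictly inside its bounds."""
    p1 = rng.uniform(0.05, 0.95)
    p2 = rng.uniform(0.05, 0.95)
    dmin, dmax = d_bounds(p1, p2)
    D = rng.uniform(margin * dmin, margin * dmax)
    eps = rng.choice(eps_choices)
    return p1, p2, D, float(eps)


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_vcf(path, samples, records):
    """records: list of (chrom, pos, ref, alt, [per-sample 'GT:AD' strings])."""
    lines = [VCF_HEADER.format(samples="\t".join(samples)).rstrip("\n")]
    for chrom, pos, ref, alt, fields in records:
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:AD\t" + "\t".join(fields)
        )
    path.write_text("\n".join(lines) + "\n")
    return str(path)
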