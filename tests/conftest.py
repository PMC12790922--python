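import numpy as np
import pytest

from mitocohort.rcrs import build_region_table


@pytest.fixture(scope="session")
def region_table():
    return build_region_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def write_vcf(path, rows, sample="S0"):
    """Write a minimal single-sample mtDNA VCF.

    rows: (pos, ref, alt, filter, ad, dp) with alt possibly comma-joined
    and ad then comma-joined per allele.
    """
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chrM,length=16569>\n"
        '##FILTER=<ID=PASS,Description="ok">\n'
        '##FILTER=<ID=base_qual,Description="bad">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="ad">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">\n'
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n"
    )
    body = ""
    for pos, ref, alt, filt, ad, dp in rows:
        ads = str(ad) if isinstance(ad, str) else str(ad)
        ref_ad = dp - sum(int(x) for x in str(ad).split(","))
        body += f"chrM\t{pos}\t.\t{ref}\t{alt}\t.\t{filt}\t.\tGT:AD:DP\t0/1:{ref_ad},{ads}:{dp}\n"
    path.write_text(header + body)
    return path
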