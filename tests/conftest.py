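import pytest

from roothair.motif_scan import RHE_CONSENSUS, parse_consensus

TOY_GFF = """##gff-version 3
chr1\ttest\tgene\t101\t400\t.\t+\t.\tID=GENE1
chr1\ttest\tmRNA\t101\t400\t.\t+\t.\tID=GENE1.1;Parent=GENE1
chr1\ttest\texon\t101\t200\t.\t+\t.\tParent=GENE1.1
chr1\ttest\texon\t301\t400\t.\t+\t.\tParent=GENE1.1
chr1\ttest\tCDS\t151\t200\t.\t+\t0\tParent=GENE1.1
chr1\ttest\tCDS\t301\t350\t.\t+\t0\tParent=GENE1.1
chr1\ttest\tgene\t601\t700\t.\t+\t.\tID=GENE2
chr1\ttest\tmRNA\t601\t700\t.\t+\t.\tID=GENE2.1;Parent=GENE2
chr1\ttest\texon\t601\t700\t.\t+\t.\tParent=GENE2.1
chr1\ttest\tCDS\t621\t680\t.\t+\t0\tParent=GENE2.1
chr2\ttest\tgene\t101\t400\t.\t-\t.\tID=GENE3
chr2\ttest\tmRNA\t101\t400\t.\t-\t.\tID=GENE3.1;Parent=GENE3
chr2\ttest\texon\t101\t200\t.\t-\t.\tParent=GENE3.1
chr2\ttest\texon\t301\t400\t.\t-\t.\tParent=GENE3.1
chr2\ttest\tCDS\t151\t200\t.\t-\t0\tParent=GENE3.1
chr2\ttest\tCDS\t301\t350\t.\t-\t0\tParent=GENE3.1
"""


@pytest.fixture
def toy_gff(tmp_path):
    p = tmp_path / "toy.gff3"
    p.write_text(TOY_GFF)
    return p


@pytest.fixture(scope="session")
def rhe():
    return parse_consensus(RHE_CONSENSUS)
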