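import textwrap

import pytest


@pytest.fixture
def write_gff(tmp_path):
    def _write(text, name="test.gff3"):
        path = tmp_path / name
        path.write_text(textwrap.dedent(text).lstrip())
        return path

    return _write


@pytest.fixture
def two_exon_gff(write_gff):
    return write_gff(
        """
        ##gff-version 3
        ##sequence-region s1 1 1000
        s1\tsrc\tgene\t101\t260\t.\t+\t.\tID=g1
        s1\tsrc\tmRNA\t101\t260\t.\t+\t.\tID=g1.t1;Parent=g1
        s1\tsrc\tCDS\t101\t160\t.\t+\t0\tParent=g1.t1
        s1\tsrc\tCDS\t201\t260\t.\t+\t0\tParent=g1.t1
        """
    )
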