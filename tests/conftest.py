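import textwrap

import pytest

from famgen import pgx


@pytest.fixture(scope="session")
def star_defs():
    return pgx.default_definitions()


@pytest.fixture
def write_text_vcf(tmp_path):
    """Write a small hand-authored VCF; body lines are tab-joined tuples."""

    def _write(body_lines, samples=("S1", "S2"), name="fixture.vcf"):
        header = textwrap.dedent(
            """\
            ##fileformat=VCFv4.2
            ##contig=<ID=1>
            ##contig=<ID=2>
            ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
            ##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
            ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
            """
        )
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT", *samples]
        path = tmp_path / name
        with open(path, "w") as fh:
            fh.write(header)
            fh.write("\t".join(cols) + "\n")
            for line in body_lines:
                fh.write("\t".join(str(x) for x in line) + "\n")
        return str(path)

    return _write
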