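import pytest

from ragmm import build_default_kb


@pytest.fixture(scope="session")
def kb():
    return build_default_kb()


@pytest.fixture
def write_vcf(tmp_path):
    """Write a minimal annotated VCF from (gene, snpeff_term) pairs."""

    def _write(records, name="input.vcf", annotation="ANN"):
        header = (
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=1,length=249250621>\n'
            f'##INFO=<ID={annotation},Number=.,Type=String,Description="x">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        lines = []
        for i, (gene, term) in enumerate(records, start=1):
            if annotation == "GENE":
                info = f"GENE={gene}"
            else:
                info = f"{annotation}=G|{term}|MODERATE|{gene}"
            lines.append(f"1\t{i * 100}\t.\tA\tG\t.\tPASS\t{info}")
        path = tmp_path / name
        path.write_text(header + "\n".join(lines) + ("\n" if lines else ""))
        return path

    return _write
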