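import numpy as np
import pytest

from sigrefit import synthetic_catalog

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##contig=<ID=chr1,length={length}>\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


@pytest.fixture(scope="session")
def catalog30():
    """The deterministic 30-signature synthetic catalog."""
    return synthetic_catalog()


@pytest.fixture(scope="session")
def reference_sequence():
    """A reproducible 10 kb random reference sequence (chr1)."""
    rng = np.random.default_rng(424242)
    return "".join(rng.choice(list("ACGT"), size=10_000))


@pytest.fixture
def write_fasta(tmp_path):
    def _write(seq, name="chr1", path=None):
        path = path or tmp_path / "ref.fa"
        with open(path, "w") as fh:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
        return str(path)

    return _write


@pytest.fixture
def write_vcf(tmp_path):
    def _write(records, length=10_000, path=None):
        """records: iterable of (pos, ref, alt) or full tab-joined body lines."""
        path = path or tmp_path / "calls.vcf"
        with open(path, "w") as fh:
            fh.write(VCF_HEADER.format(length=length))
            for rec in records:
                if isinstance(rec, str):
                    fh.write(rec + "\n")
                else:
                    pos, ref, alt = rec
                    fh.write(f"chr1\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\n")
        return str(path)

    return _write
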