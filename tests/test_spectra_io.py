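"""Spectrum/catalog text round trips and VCF-to-spectrum counting."""

import numpy as np
import pandas as pd
import pytest

from sigrefit import (
    MutationSpectrum,
    SignatureCatalog,
    read_signature_catalog,
    read_spectrum,
    synthetic_catalog,
    vcf_to_spectrum,
    write_signature_catalog,
    write_spectrum,
)
from sigrefit.contexts import CONTEXT_INDEX, CONTEXT_LABELS


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


def test_spectrum_validates_shape_and_sign():
    with pytest.raises(ValueError):
        MutationSpectrum(np.zeros(95))
    with pytest.raises(ValueError):
        MutationSpectrum(np.full(96, -1))
    with pytest.raises(ValueError):
        MutationSpectrum(np.full(96, 0.5))
    s = MutationSpectrum(np.arange(96))
    assert s.total == int(np.arange(96).sum())


def test_catalog_rejects_non_stochastic_columns():
    P = np.full((96, 2), 1 / 96)
    P[:, 1] *= 0.9
    with pytest.raises(ValueError):
        SignatureCatalog(P, ["a", "b"])


# ---------------------------------------------------------------------------
# text round trips
# ---------------------------------------------------------------------------


def test_spectrum_roundtrip_is_exact(tmp_path):
    rng = np.random.default_rng(1)
    spec = MutationSpectrum(rng.integers(0, 50, size=96), sample_id="s1")
    path = tmp_path / "spec.tsv"
    write_spectrum(spec, path)
    back = read_spectrum(path)
    assert np.array_equal(back.counts, spec.counts)
    assert back.sample_id == "s1"


def test_catalog_row_order_is_irrelevant(tmp_path, catalog30):
    sorted_path = tmp_path / "sorted.tsv"
    write_signature_catalog(catalog30, sorted_path)
    df = pd.read_csv(sorted_path, sep="\t", comment="#")
    shuffled_path = tmp_path / "shuffled.tsv"
    df.sample(frac=1.0, random_state=7).to_csv(shuffled_path, sep="\t", index=False)
    a = read_signature_catalog(sorted_path)
    b = read_signature_catalog(shuffled_path)
    assert a.signature_names == b.signature_names
    assert np.array_equal(a.probabilities, b.probabilities)


def test_catalog_column_summing_to_0p9_is_rejected(tmp_path, catalog30):
    path = tmp_path / "bad.tsv"
    df = pd.DataFrame({"Somatic Mutation Type": CONTEXT_LABELS})
    df["sigA"] = catalog30.probabilities[:, 0] * 0.9
    df.to_csv(path, sep="\t", index=False)
    with pytest.raises(ValueError, match="sum to 1"):
        read_signature_catalog(path)


def test_catalog_duplicate_and_missing_labels_are_reported(tmp_path, catalog30):
    path = tmp_path / "dup.tsv"
    df = pd.DataFrame(
        {"ctx": CONTEXT_LABELS, "sigA": catalog30.probabilities[:, 0]}
    )
    df.loc[1, "ctx"] = df.loc[0, "ctx"]  # duplicate one label, lose another
    df.to_csv(path, sep="\t", index=False)
    with pytest.raises(ValueError, match="duplicated"):
        read_signature_catalog(path)


def test_negative_count_is_rejected(tmp_path):
    path = tmp_path / "neg.tsv"
    df = pd.DataFrame({"context": CONTEXT_LABELS, "s": [1] * 96})
    df.loc[0, "s"] = -1
    df.to_csv(path, sep="\t", index=False)
    with pytest.raises(ValueError, match="negative"):
        read_spectrum(path)


def test_bundled_catalog_loads_30_signatures():
    from sigrefit import default_catalog

    cat = default_catalog()
    assert cat.n_signatures == 30
    assert np.allclose(cat.probabilities.sum(axis=0), 1.0, atol=1e-9)
    # bundled file reproduces the generator to write precision
    assert np.allclose(
        cat.probabilities, synthetic_catalog().probabilities, atol=1e-9
    )


# ---------------------------------------------------------------------------
# VCF counting
# ---------------------------------------------------------------------------


def test_single_snv_increments_exactly_one_context(write_fasta, write_vcf):
    fasta = write_fasta("GGACAGG")  # pos 4 is C with flanks A..A
    vcf = write_vcf([(4, "C", "T")], length=7)
    spec, report = vcf_to_spectrum(vcf, fasta)
    assert spec.total == 1
    assert report.total == 0
    assert spec.counts[CONTEXT_INDEX["A[C>T]A"]] == 1


def test_non_snv_and_multiallelic_records_are_skipped(write_fasta, write_vcf):
    fasta = write_fasta("GGACAGG")
    vcf = write_vcf(
        [
            "chr1\t4\t.\tCA\tC\t.\t.\t.",  # deletion
            "chr1\t4\t.\tC\tT,G\t.\t.\t.",  # multi-allelic
            "chr1\t1\t.\tG\tA\t.\t.\t.",  # contig boundary (no 5' flank)
            (4, "C", "T"),
        ],
        length=7,
    )
    spec, report = vcf_to_spectrum(vcf, fasta)
    assert spec.total == 1
    assert report.not_snv == 1
    assert report.multiallelic == 1
    assert report.contig_boundary == 1


def test_empty_vcf_yields_zero_spectrum_with_warning(write_fasta, write_vcf):
    fasta = write_fasta("GGACAGG")
    vcf = write_vcf([], length=7)
    with pytest.warns(UserWarning, match="no records"):
        spec, report = vcf_to_spectrum(vcf, fasta)
    assert spec.total == 0 and report.total == 0


def test_unknown_contig_is_a_hard_error(write_fasta, tmp_path):
    fasta = write_fasta("GGACAGG")
    vcf = tmp_path / "other.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n##contig=<ID=chrX,length=7>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chrX\t4\t.\tC\tT\t.\t.\t.\n"
    )
    with pytest.raises(ValueError, match="chrX"):
        vcf_to_spectrum(str(vcf), fasta)


def _oracle_count(seq, records):
    """Independent brute-force context counter over (pos, ref, alt) records."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    counts = dict.fromkeys(CONTEXT_LABELS, 0)
    for pos, ref, alt in records:
        f5, f3 = seq[pos - 2], seq[pos]
        if ref in "CT":
            lab = f"{f5}[{ref}>{alt}]{f3}"
        else:
            lab = f"{comp[f3]}[{comp[ref]}>{comp[alt]}]{comp[f5]}"
        counts[lab] += 1
    return np.array([counts[lab] for lab in CONTEXT_LABELS])


def test_hundred_snvs_match_brute_force_oracle(
    reference_sequence, write_fasta, write_vcf
):
    rng = np.random.default_rng(99)
    records = []
    for pos in sorted(rng.choice(np.arange(2, 9999), size=100, replace=False)):
        ref = reference_sequence[pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        records.append((int(pos), ref, str(alt)))
    fasta = write_fasta(reference_sequence)
    vcf = write_vcf(records)
    spec, report = vcf_to_spectrum(vcf, fasta)
    assert report.total == 0
    assert spec.total == 100
    assert np.array_equal(spec.counts, _oracle_count(reference_sequence, records))
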