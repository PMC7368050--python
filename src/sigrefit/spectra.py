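"""Mutation spectra and signature catalogs: containers and text/VCF I/O.

A :class:`MutationSpectrum` holds the integer counts of one sample over the
96 canonical contexts. A :class:`SignatureCatalog` holds a column-stochastic
96 x K matrix of signature probability distributions. Both are (de)serialized
as tab-separated text keyed by context label; file row order is irrelevant,
rows are always re-indexed to the canonical order of
:data:`sigrefit.contexts.CONTEXT_LABELS`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contexts import (
    CONTEXT_LABELS,
    N_CONTEXTS,
    InvalidVariantError,
    UnclassifiableContextError,
    classify_substitution,
)

_CATALOG_COLSUM_TOL = 1e-3  # columns are renormalized if within this of 1
_CATALOG_STRICT_TOL = 1e-6


@dataclass
class MutationSpectrum:
    """Counts of somatic SNVs over the 96 trinucleotide contexts for one sample."""

    counts: np.ndarray
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (N_CONTEXTS,):
            raise ValueError(f"spectrum must have length {N_CONTEXTS}, got {c.shape}")
        if not np.all(np.isfinite(c)) or np.any(c < 0):
            raise ValueError("spectrum counts must be finite and non-negative")
        if not np.all(c == np.floor(c)):
            raise ValueError("spectrum counts must be integers")
        self.counts = c.astype(np.int64)

    @property
    def total(self) -> int:
        """N, the total mutation count."""
        return int(self.counts.sum())

    def mle(self) -> np.ndarray:
        """Multinomial maximum-likelihood context distribution, counts / N."""
        if self.total == 0:
            raise ValueError("cannot form the MLE of an empty spectrum")
        return self.counts / self.total


@dataclass
class SignatureCatalog:
    """Column-stochastic 96 x K matrix of known mutational signatures."""

    probabilities: np.ndarray
    signature_names: list[str]
    context_labels: tuple[str, ...] = field(default=CONTEXT_LABELS)

    def __post_init__(self) -> None:
        P = np.asarray(self.probabilities, dtype=float)
        if P.ndim != 2 or P.shape[0] != N_CONTEXTS:
            raise ValueError(f"catalog must be {N_CONTEXTS} x K, got {P.shape}")
        if P.shape[1] != len(self.signature_names):
            raise ValueError("number of signature names does not match columns")
        if np.any(P < 0) or not np.all(np.isfinite(P)):
            raise ValueError("signature probabilities must be finite and >= 0")
        sums = P.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > _CATALOG_STRICT_TOL):
            raise ValueError(
                "signature columns must each sum to 1: "
                f"offending sums {sums[np.abs(sums - 1.0) > _CATALOG_STRICT_TOL]}"
            )
        self.probabilities = P
        self.signature_names = list(self.signature_names)

    @property
    def n_signatures(self) -> int:
        return self.probabilities.shape[1]

    def subset(self, names: list[str]) -> "SignatureCatalog":
        idx = [self.signature_names.index(n) for n in names]
        return SignatureCatalog(self.probabilities[:, idx], list(names))


# ---------------------------------------------------------------------------
# text I/O
# ---------------------------------------------------------------------------


def _find_context_column(df: pd.DataFrame) -> str:
    wanted = set(CONTEXT_LABELS)
    for col in df.columns:
        if set(df[col].astype(str)) & wanted:
            return col
    raise ValueError(
        "no column containing the 96 canonical context labels (e.g. 'A[C>T]G') found"
    )


def _reindex_contexts(df: pd.DataFrame, label_col: str) -> pd.DataFrame:
    labels = df[label_col].astype(str)
    dup = labels[labels.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicated context labels: {dup}")
    missing = sorted(set(CONTEXT_LABELS) - set(labels))
    if missing:
        raise ValueError(f"missing context labels: {missing}")
    out = df.set_index(label_col)
    return out.loc[list(CONTEXT_LABELS)]


def read_signature_catalog(path: str | Path) -> SignatureCatalog:
    """Read a tab-separated signature catalog (COSMIC v2 style layout).

    Rows are keyed by a column holding the 96 context labels; any other
    non-numeric columns (e.g. substitution type / trinucleotide helper
    columns) are ignored. Columns are renormalized to sum exactly to 1 when
    within 1e-3 of 1, otherwise an error is raised.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    label_col = _find_context_column(df)
    df = _reindex_contexts(df, label_col)
    num = df.select_dtypes(include=[np.number])
    if num.shape[1] == 0:
        raise ValueError("catalog file contains no numeric signature columns")
    P = num.to_numpy(dtype=float)
    if np.any(P < 0):
        raise ValueError("negative signature probability in catalog")
    sums = P.sum(axis=0)
    bad = np.abs(sums - 1.0) > _CATALOG_COLSUM_TOL
    if np.any(bad):
        offenders = {num.columns[i]: float(sums[i]) for i in np.where(bad)[0]}
        raise ValueError(f"signature columns do not sum to 1 within 1e-3: {offenders}")
    P = P / sums
    return SignatureCatalog(P, [str(c) for c in num.columns])


def write_signature_catalog(catalog: SignatureCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sigrefit v{__version__} signature catalog\n")
        fh.write("Somatic Mutation Type\t" + "\t".join(catalog.signature_names) + "\n")
        for i, lab in enumerate(CONTEXT_LABELS):
            row = "\t".join(f"{v:.10g}" for v in catalog.probabilities[i])
            fh.write(f"{lab}\t{row}\n")


def read_spectrum(path: str | Path, sample: str | None = None) -> MutationSpectrum:
    """Read a spectrum from a two-column (context, count) or 96 x S table.

    For multi-sample tables ``sample`` selects the column; default is the
    first sample column.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    label_col = _find_context_column(df)
    df = _reindex_contexts(df, label_col)
    num = df.select_dtypes(include=[np.number])
    if num.shape[1] == 0:
        raise ValueError("spectrum file contains no count column")
    if sample is None:
        col = num.columns[0]
    elif sample in num.columns:
        col = sample
    else:
        raise ValueError(f"sample {sample!r} not in file columns {list(num.columns)}")
    counts = num[col].to_numpy()
    if np.any(counts < 0):
        raise ValueError("negative count in spectrum file")
    return MutationSpectrum(counts, sample_id=str(col))


def write_spectrum(spectrum: MutationSpectrum, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sigrefit v{__version__} mutation spectrum\n")
        fh.write(f"context\t{spectrum.sample_id}\n")
        for lab, cnt in zip(CONTEXT_LABELS, spectrum.counts):
            fh.write(f"{lab}\t{int(cnt)}\n")


# ---------------------------------------------------------------------------
# VCF -> spectrum
# ---------------------------------------------------------------------------


@dataclass
class SkipReport:
    """Tally of VCF records excluded from a spectrum, by reason."""

    not_snv: int = 0
    multiallelic: int = 0
    n_in_context: int = 0
    contig_boundary: int = 0
    ref_mismatch: int = 0
    filtered: int = 0
    no_sample_genotype: int = 0

    @property
    def total(self) -> int:
        return (
            self.not_snv
            + self.multiallelic
            + self.n_in_context
            + self.contig_boundary
            + self.ref_mismatch
            + self.filtered
            + self.no_sample_genotype
        )

    def summary(self) -> str:
        parts = [
            f"{name}={getattr(self, name)}"
            for name in (
                "not_snv",
                "multiallelic",
                "n_in_context",
                "contig_boundary",
                "ref_mismatch",
                "filtered",
                "no_sample_genotype",
            )
            if getattr(self, name)
        ]
        return f"skipped {self.total} record(s)" + (
            f" ({', '.join(parts)})" if parts else ""
        )


def vcf_to_spectrum(
    vcf_source: str | Path,
    fasta_source: str | Path,
    sample_id: str | None = None,
    pass_only: bool = False,
) -> tuple[MutationSpectrum, SkipReport]:
    """Count biallelic SNVs from a VCF into a 96-context spectrum.

    Flanking bases are read from the reference FASTA at pos-1 and pos+1
    (1-based VCF coordinates); soft-masked lowercase bases are uppercased.
    Indels, multi-allelic records, records with N in the trinucleotide and
    records at contig boundaries are skipped and tallied in the returned
    :class:`SkipReport`. By default all records are pooled regardless of
    genotype; if ``sample_id`` names a VCF sample column, only records where
    that sample carries a non-reference genotype are counted.
    """
    from cyvcf2 import VCF
    from pyfaidx import Fasta

    fasta = Fasta(str(fasta_source))
    vcf = VCF(str(vcf_source))
    sample_idx: int | None = None
    if sample_id is not None and sample_id in vcf.samples:
        sample_idx = vcf.samples.index(sample_id)

    counts = np.zeros(N_CONTEXTS, dtype=np.int64)
    report = SkipReport()
    n_records = 0
    for rec in vcf:
        n_records += 1
        if pass_only and rec.FILTER is not None:  # cyvcf2: None means PASS/'.'
            report.filtered += 1
            continue
        if len(rec.ALT) != 1:
            report.multiallelic += 1
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref.upper() == alt.upper():
            report.not_snv += 1
            continue
        if alt.upper() not in "ACGT" or ref.upper() not in "ACGT":
            report.not_snv += 1
            continue
        if rec.CHROM not in fasta:
            raise ValueError(f"contig {rec.CHROM!r} absent from FASTA")
        if sample_idx is not None:
            gt = rec.genotypes[sample_idx]
            if not any(a == 1 for a in gt[:-1]):
                report.no_sample_genotype += 1
                continue
        contig = fasta[rec.CHROM]
        pos = rec.POS  # 1-based
        if pos <= 1 or pos >= len(contig):
            report.contig_boundary += 1
            continue
        tri = contig[pos - 2 : pos + 1].seq.upper()
        if any(b not in "ACGT" for b in tri):
            report.n_in_context += 1
            continue
        if tri[1] != ref.upper():
            report.ref_mismatch += 1
            continue
        try:
            ctx = classify_substitution(ref, alt, tri[0], tri[2])
        except (InvalidVariantError, UnclassifiableContextError):
            report.not_snv += 1
            continue
        counts[ctx.index] += 1

    if n_records == 0:
        warnings.warn("VCF contained no records; returning an all-zero spectrum")
    name = sample_id if sample_id is not None else Path(str(vcf_source)).stem
    return MutationSpectrum(counts, sample_id=name), report
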