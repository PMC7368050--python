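"""Canonical 96 trinucleotide substitution contexts.

Single-base substitutions are reported on the pyrimidine strand: a variant
whose reference base is a purine (A or G) is reverse-complemented, flanks
included, so that every substitution reads as C>X or T>X. With 6 substitution
classes and 4 choices for each flanking base this yields the canonical
96 contexts, written ``F[R>A]T`` (5' flank, ref>alt, 3' flank).

The canonical ordering — substitution class major (C>A, C>G, C>T, T>A, T>C,
T>G), then 5' flank, then 3' flank, both alphabetical — is the single source
of truth for every vector and matrix row index in this package and matches
the published COSMIC v2 row order.
"""

from __future__ import annotations

from dataclasses import dataclass

BASES = ("A", "C", "G", "T")
PYRIMIDINES = ("C", "T")
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Canonical context labels, index 0..95. Class-major, then 5' then 3' flank.
CONTEXT_LABELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in BASES
    for three in BASES
)

CONTEXT_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(CONTEXT_LABELS)}

N_CONTEXTS = 96

#: substitution class of context i is ``i // 16`` under the canonical order.
CONTEXTS_PER_CLASS = 16


class InvalidVariantError(ValueError):
    """Raised when a variant is not a valid substitution (e.g. ref == alt)."""


class UnclassifiableContextError(ValueError):
    """Raised when a base outside {A,C,G,T} (e.g. N) prevents classification."""


@dataclass(frozen=True)
class SubstitutionContext:
    """A pyrimidine-normalized single-base substitution with its flanks."""

    ref_pyrimidine: str
    alt: str
    five_prime: str
    three_prime: str

    @property
    def label(self) -> str:
        return f"{self.five_prime}[{self.ref_pyrimidine}>{self.alt}]{self.three_prime}"

    @property
    def index(self) -> int:
        return CONTEXT_INDEX[self.label]


def _check_base(b: str, what: str) -> str:
    b = b.upper()
    if b not in _COMPLEMENT:
        raise UnclassifiableContextError(f"{what} base {b!r} is not one of A/C/G/T")
    return b


def classify_substitution(
    ref: str, alt: str, five_prime: str, three_prime: str
) -> SubstitutionContext:
    """Map a raw substitution and its flanking bases onto its canonical context.

    Purine-reference variants are reverse-complemented (the flanks swap
    roles) so the returned reference base is always C or T.

    Raises
    ------
    InvalidVariantError
        If ``ref == alt``.
    UnclassifiableContextError
        If any base is outside {A, C, G, T}.
    """
    ref = _check_base(ref, "ref")
    alt = _check_base(alt, "alt")
    five_prime = _check_base(five_prime, "5' flank")
    three_prime = _check_base(three_prime, "3' flank")
    if ref == alt:
        raise InvalidVariantError(f"ref and alt are both {ref!r}")
    if ref in PYRIMIDINES:
        return SubstitutionContext(ref, alt, five_prime, three_prime)
    # purine strand: reverse complement, flanks swap
    return SubstitutionContext(
        _COMPLEMENT[ref],
        _COMPLEMENT[alt],
        _COMPLEMENT[three_prime],
        _COMPLEMENT[five_prime],
    )


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
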