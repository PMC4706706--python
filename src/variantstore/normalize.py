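"""Canonical left-aligned representation of small variants.

Every distinct spelling of one edit (right-shifted within a repeat tract,
carrying redundant shared flanking context, etc.) is reduced to a single
canonical form: the leftmost position at which the edit can be placed, with
all shared prefix/suffix context trimmed except for the single 5' anchor
base that length-changing variants retain (VCF convention — REF and ALT are
never empty, and an insertion can never collide with an SNV at the same
start because their alt lengths differ). Pure substitutions are fully
trimmed. A variant at contig position 1 with no 5' base available keeps a
3' anchor instead and is flagged.

Chromosomes are also given a numeric code (1..22, X=23, Y=24, MT=25) used
inside variant keys and for fast indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import (
    NormalizationError,
    ReferenceMismatchError,
    UnknownContigError,
)
from .reference import contig_length, fetch_span

__all__ = [
    "RawVariant",
    "NormalizedVariant",
    "chrom_code",
    "left_align",
    "classify",
    "effective_size",
    "is_small_indel",
    "SMALL_INDEL_MAX_SIZE",
]

#: indels of effective size (|len(ref)-len(alt)|) up to this are "small".
SMALL_INDEL_MAX_SIZE = 1000

VTYPES = ("SNV", "MNV", "INS", "DEL", "INSDEL")


@dataclass(frozen=True)
class RawVariant:
    """A variant as spelled in an input file: 1-based position, REF, ALT."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True, order=True)
class NormalizedVariant:
    """Canonical left-aligned variant.

    ``start``/``end`` are 1-based inclusive with ``end == start + len(ref) - 1``.
    ``ref``/``alt``/``vtype``/``effective_size`` may be None on variants
    reconstructed from a key without a reference at hand.
    """

    build_code: int
    chrom: str
    chrom_code: int
    start: int
    end: int
    ref: Optional[str]
    alt: Optional[str]
    vtype: Optional[str] = None
    effective_size: Optional[int] = None
    anchor_3prime: bool = field(default=False, compare=False)

    @property
    def identity(self) -> tuple:
        """The deduplication identity: one record per such tuple."""
        return (self.build_code, self.chrom_code, self.start, self.end, self.alt)


def chrom_code(name: str) -> int:
    """Numeric chromosome code: 1..22, X=23, Y=24, MT=25.

    Case-insensitive; an optional "chr" prefix is stripped; "M" is accepted
    for the mitochondrial contig. Unplaced scaffolds are rejected.
    """
    s = name.strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper()
    if s == "M":
        s = "MT"
    if s == "X":
        return 23
    if s == "Y":
        return 24
    if s == "MT":
        return 25
    if s.isdigit() and 1 <= int(s) <= 22:
        return int(s)
    raise UnknownContigError(f"unsupported contig name: {name!r}")


def classify(ref: str, alt: str) -> str:
    """Variant type of a trimmed, anchored REF/ALT pair.

    SNV: both length 1. MNV: equal lengths > 1. INS: ALT extends REF, which
    is its anchor prefix. DEL: symmetric. INSDEL: simultaneous unequal-length
    replacement fitting none of the above.
    """
    if ref == alt:
        raise NormalizationError("ref and alt are identical")
    if len(ref) == len(alt):
        return "SNV" if len(ref) == 1 else "MNV"
    if len(alt) > len(ref) and alt.startswith(ref):
        return "INS"
    if len(ref) > len(alt) and ref.startswith(alt):
        return "DEL"
    return "INSDEL"


def effective_size(ref: str, alt: str) -> int:
    """Absolute length difference of REF and ALT (0 for substitutions)."""
    return abs(len(ref) - len(alt))


def is_small_indel(ref: str, alt: str) -> bool:
    """True iff the effective size is at most 1000 bp."""
    return effective_size(ref, alt) <= SMALL_INDEL_MAX_SIZE


def left_align(raw: RawVariant, reference, build_code: int = 37) -> NormalizedVariant:
    """Left-align, trim and classify a raw variant against the reference.

    Idempotent; every equivalent spelling of one edit maps to the same
    output (and hence the same variant key). Raises
    :class:`ReferenceMismatchError` if the spelled REF disagrees with the
    reference sequence and :class:`NormalizationError` on out-of-bounds
    coordinates.
    """
    code = chrom_code(raw.chrom)
    pos = raw.pos
    ref = raw.ref.upper()
    alt = raw.alt.upper()
    if not ref or not alt:
        raise NormalizationError(
            f"empty REF or ALT at {raw.chrom}:{raw.pos} (anchored spelling required)"
        )
    if ref == alt:
        raise NormalizationError(f"REF equals ALT at {raw.chrom}:{raw.pos}")
    clen = contig_length(reference, raw.chrom)
    if pos < 1 or pos + len(ref) - 1 > clen:
        raise NormalizationError(
            f"variant {raw.chrom}:{pos} {ref}>{alt} out of contig bounds (1..{clen})"
        )
    observed = fetch_span(reference, raw.chrom, pos, pos + len(ref) - 1)
    if observed != ref:
        raise ReferenceMismatchError(
            f"REF {ref!r} does not match reference {observed!r} at {raw.chrom}:{pos}"
        )

    anchor_3prime = False
    # Shift left while the rightmost bases agree, extending with reference
    # bases whenever an allele would empty out.
    while True:
        if ref[-1] == alt[-1] and not (len(ref) == 1 and len(alt) == 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 1:
                    # no 5' base available: keep a 3' anchor instead
                    b = fetch_span(
                        reference, raw.chrom, pos + max(len(ref), len(alt)),
                        pos + max(len(ref), len(alt)),
                    )
                    ref, alt = ref + b, alt + b
                    anchor_3prime = True
                    break
                b = fetch_span(reference, raw.chrom, pos - 1, pos - 1)
                ref, alt = b + ref, b + alt
                pos -= 1
        else:
            break
    # Trim redundant shared leading context (keep the anchor base).
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1

    vtype = classify(ref, alt)
    return NormalizedVariant(
        build_code=build_code,
        chrom=_canonical_name(raw.chrom),
        chrom_code=code,
        start=pos,
        end=pos + len(ref) - 1,
        ref=ref,
        alt=alt,
        vtype=vtype,
        effective_size=effective_size(ref, alt),
        anchor_3prime=anchor_3prime,
    )


def _canonical_name(chrom: str) -> str:
    s = chrom.strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper()
    return "MT" if s == "M" else s
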