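"""Reversible, byte-sortable variant key codec.

A variant key is a fixed-layout base-64 string identifying one normalized
small variant on one genome build:

====================  =======  ==========================================
field                 width    content
====================  =======  ==========================================
build                 1        GRCh build number (e.g. 37) as one symbol
chromosome            1        1..22, X=23, Y=24, MT=25 as one symbol
start                 5        1-based start position, big-endian
end                   5        1-based end position (start+len(ref)-1)
alt length            2        length of the alternate allele (0..4095)
packed alt allele     rest     3 nucleotides per symbol (A,C,G,T = 0..3)
====================  =======  ==========================================

The 64-symbol alphabet (digits, '@', upper case, '_', lower case) is strictly
increasing in byte order, so byte-wise sorting of key strings equals sorting
by (build, chromosome, start, end, alt length, alt allele) — genomic order.
Keys are capped at :data:`MAX_KEY_LEN` characters; alleles up to
:data:`MAX_UNIQUE_ALT_LEN` nucleotides are encoded losslessly, longer ones
are truncated and the key flagged non-unique (such variants must be looked
up by location and alternate allele instead).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

from .errors import AlleleError, KeyCodecError, NonUniqueKeyWarning

__all__ = [
    "ALPHABET",
    "HEADER_LEN",
    "MAX_KEY_LEN",
    "MAX_ALT_LEN_FIELD",
    "MAX_UNIQUE_ALT_LEN",
    "VariantKey",
    "encode_int",
    "decode_int",
    "pack_allele",
    "unpack_allele",
    "encode_key",
    "decode_key",
    "range_prefix",
    "chrom_name",
]

#: 64 symbols in strictly increasing byte order: digits, '@', A-Z, '_', a-z.
ALPHABET = (
    "0123456789@ABCDEFGHIJKLMNOPQRSTUVWXYZ_abcdefghijklmnopqrstuvwxyz"
)
_INDEX = {c: i for i, c in enumerate(ALPHABET)}
assert len(ALPHABET) == 64 and len(_INDEX) == 64

#: fixed header: 1 build + 1 chrom + 5 start + 5 end + 2 alt-length symbols.
HEADER_LEN = 14
#: total key length cap (embedded-index friendly).
MAX_KEY_LEN = 1000
#: capacity of the two-symbol alt-length field.
MAX_ALT_LEN_FIELD = 64 * 64 - 1  # 4095
#: longest alt allele representable losslessly under the key-length cap.
MAX_UNIQUE_ALT_LEN = (MAX_KEY_LEN - HEADER_LEN) * 3  # 2958

_NUC2BITS = {"A": 0, "C": 1, "G": 2, "T": 3}
_BITS2NUC = "ACGT"

_CHROM_NAMES = {**{i: str(i) for i in range(1, 23)}, 23: "X", 24: "Y", 25: "MT"}


def chrom_name(code: int) -> str:
    """Contig name for a numeric chromosome code (23=X, 24=Y, 25=MT)."""
    try:
        return _CHROM_NAMES[code]
    except KeyError:
        raise KeyCodecError(f"chromosome code out of range 1..25: {code}") from None


@dataclass(frozen=True)
class VariantKey:
    """A variant key string together with its parsed fields.

    ``unique`` is True iff the alternate allele is fully representable
    within the key-length cap, i.e. the key decodes back losslessly.
    """

    text: str
    build_code: int
    chrom_code: int
    start: int
    end: int
    alt_len: int
    alt_packed: str
    unique: bool


def encode_int(value: int, width: int) -> str:
    """Encode a non-negative integer as a fixed-width big-endian base-64 string.

    At fixed width, numeric order of values equals byte order of outputs.
    """
    if width <= 0:
        raise KeyCodecError(f"width must be positive, got {width}")
    if value < 0:
        raise KeyCodecError(f"cannot encode negative value {value}")
    if value >= 64**width:
        raise KeyCodecError(f"value {value} does not fit in {width} base-64 symbols")
    out = []
    for _ in range(width):
        out.append(ALPHABET[value & 63])
        value >>= 6
    return "".join(reversed(out))


def decode_int(text: str) -> int:
    """Inverse of :func:`encode_int` (any positive width)."""
    if not text:
        raise KeyCodecError("cannot decode empty string")
    value = 0
    for c in text:
        try:
            value = (value << 6) | _INDEX[c]
        except KeyError:
            raise KeyCodecError(f"character {c!r} outside the key alphabet") from None
    return value


def pack_allele(seq: str) -> str:
    """Pack an ACGT string, 3 nucleotides per base-64 symbol.

    Trailing positions of the final triplet are zero-padded; the separately
    stored allele length disambiguates, making the packing lossless.
    """
    out = []
    for i in range(0, len(seq), 3):
        triplet = seq[i : i + 3]
        value = 0
        for j in range(3):
            if j < len(triplet):
                try:
                    value = (value << 2) | _NUC2BITS[triplet[j]]
                except KeyError:
                    raise AlleleError(
                        f"non-ACGT character {triplet[j]!r} in allele"
                    ) from None
            else:
                value <<= 2
        out.append(ALPHABET[value])
    return "".join(out)


def unpack_allele(packed: str, alt_len: int) -> str:
    """Inverse of :func:`pack_allele` given the original allele length."""
    if alt_len < 0:
        raise AlleleError(f"negative allele length {alt_len}")
    if len(packed) != math.ceil(alt_len / 3):
        raise AlleleError(
            f"packed length {len(packed)} inconsistent with allele length {alt_len}"
        )
    out = []
    for c in packed:
        try:
            value = _INDEX[c]
        except KeyError:
            raise KeyCodecError(f"character {c!r} outside the key alphabet") from None
        out.append(_BITS2NUC[(value >> 4) & 3])
        out.append(_BITS2NUC[(value >> 2) & 3])
        out.append(_BITS2NUC[value & 3])
    return "".join(out)[:alt_len]


def encode_key(v) -> VariantKey:
    """Encode a normalized variant as a :class:`VariantKey`.

    ``v`` needs attributes ``build_code``, ``chrom_code``, ``start``, ``end``
    and ``alt`` (a :class:`~variantstore.normalize.NormalizedVariant` or any
    duck-typed equivalent). Alleles containing characters outside A/C/G/T
    (N, IUPAC codes, symbolic ALTs) yield a non-unique key with an empty
    packed allele; such records must be accessed by location + alt allele.
    """
    build, chrom = v.build_code, v.chrom_code
    if not 0 <= build < 64:
        raise KeyCodecError(f"build code {build} not representable in one symbol")
    if not 1 <= chrom <= 25:
        raise KeyCodecError(f"chromosome code out of range 1..25: {chrom}")
    alt = v.alt.upper()
    alt_len = len(alt)
    if alt_len > MAX_ALT_LEN_FIELD:
        raise KeyCodecError(
            f"alternate allele length {alt_len} exceeds field capacity "
            f"{MAX_ALT_LEN_FIELD}"
        )
    header = (
        ALPHABET[build]
        + ALPHABET[chrom]
        + encode_int(v.start, 5)
        + encode_int(v.end, 5)
        + encode_int(alt_len, 2)
    )
    try:
        packed = pack_allele(alt)
    except AlleleError:
        # non-ACGT allele: key carries position + length only
        packed, unique = "", False
    else:
        if alt_len > MAX_UNIQUE_ALT_LEN:
            packed = packed[: MAX_KEY_LEN - HEADER_LEN]
            unique = False
        else:
            unique = True
    return VariantKey(
        text=header + packed,
        build_code=build,
        chrom_code=chrom,
        start=v.start,
        end=v.end,
        alt_len=alt_len,
        alt_packed=packed,
        unique=unique,
    )


def decode_key(text: str, reference=None):
    """Decode a key string back into a normalized variant.

    The REF allele is filled from ``reference`` (a mapping/pyfaidx ``Fasta``
    of contig name → sequence) over the span start..end when provided,
    otherwise left unset. For keys flagged non-unique a
    :class:`~variantstore.errors.NonUniqueKeyWarning` is issued: the decoded
    allele may be truncated (or absent for non-ACGT alleles).
    """
    from .normalize import NormalizedVariant, classify, effective_size
    from .reference import fetch_span

    if len(text) < HEADER_LEN:
        raise KeyCodecError(f"key shorter than {HEADER_LEN} characters: {text!r}")
    if len(text) > MAX_KEY_LEN:
        raise KeyCodecError(f"key longer than {MAX_KEY_LEN} characters")
    build = decode_int(text[0])
    chrom = decode_int(text[1])
    if not 1 <= chrom <= 25:
        raise KeyCodecError(f"chromosome symbol decodes to {chrom}, outside 1..25")
    start = decode_int(text[2:7])
    end = decode_int(text[7:12])
    alt_len = decode_int(text[12:14])
    packed = text[HEADER_LEN:]
    expected = math.ceil(alt_len / 3)
    unique = alt_len <= MAX_UNIQUE_ALT_LEN and len(packed) == expected
    if unique:
        alt: Optional[str] = unpack_allele(packed, alt_len)
    else:
        warnings.warn(
            f"key {text[:20]}... is non-unique: allele may be truncated",
            NonUniqueKeyWarning,
            stacklevel=2,
        )
        if len(packed) > expected:
            raise KeyCodecError(
                "packed allele longer than the declared allele length allows"
            )
        alt = unpack_allele(packed, min(alt_len, len(packed) * 3)) if packed else None
    name = chrom_name(chrom)
    ref = None
    if reference is not None:
        ref = fetch_span(reference, name, start, end)
    vtype = size = None
    if ref is not None and alt is not None and unique and ref != alt:
        vtype = classify(ref, alt)
        size = effective_size(ref, alt)
    return NormalizedVariant(
        build_code=build,
        chrom=name,
        chrom_code=chrom,
        start=start,
        end=end,
        ref=ref,
        alt=alt,
        vtype=vtype,
        effective_size=size,
    )


def range_prefix(
    build: int, chrom_code: int, start_lo: int, start_hi: int
) -> tuple[str, str]:
    """Inclusive byte-wise key bounds selecting a (build, chrom, start) window.

    A variant key ``k`` satisfies ``lo <= k <= hi`` iff its build, chromosome
    and start position fall inside the requested window — the basis for
    prefix range scans over a byte-sorted key index.
    """
    if start_lo > start_hi:
        raise KeyCodecError(f"inverted window: {start_lo} > {start_hi}")
    if not 0 <= build < 64:
        raise KeyCodecError(f"build code {build} not representable in one symbol")
    if not 1 <= chrom_code <= 25:
        raise KeyCodecError(f"chromosome code out of range 1..25: {chrom_code}")
    prefix = ALPHABET[build] + ALPHABET[chrom_code]
    lo = prefix + encode_int(start_lo, 5)
    hi = prefix + encode_int(start_hi, 5) + ALPHABET[-1] * (MAX_KEY_LEN - 7)
    return lo, hi
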