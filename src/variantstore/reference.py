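"""Uniform access to reference sequences.

Accepts either a plain mapping of contig name → sequence string (as produced
by tests and the synthetic module) or a :class:`pyfaidx.Fasta` opened on an
indexed FASTA file. Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from .errors import NormalizationError, UnknownContigError


def _lookup_contig(reference, chrom: str):
    candidates = [chrom]
    if chrom.startswith("chr"):
        candidates.append(chrom[3:])
    else:
        candidates.append("chr" + chrom)
    for name in candidates:
        try:
            return reference[name]
        except KeyError:
            continue
    raise UnknownContigError(f"contig {chrom!r} not present in the reference")


def fetch_span(reference, chrom: str, start: int, end: int) -> str:
    """Reference bases over [start, end], 1-based inclusive, upper-cased."""
    if start < 1 or end < start - 1:
        raise NormalizationError(f"invalid span {chrom}:{start}-{end}")
    if end < start:  # zero-length span
        return ""
    contig = _lookup_contig(reference, chrom)
    if end > len(contig):
        raise NormalizationError(
            f"span {chrom}:{start}-{end} beyond contig length {len(contig)}"
        )
    return str(contig[start - 1 : end]).upper()


def contig_length(reference, chrom: str) -> int:
    return len(_lookup_contig(reference, chrom))
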