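"""VCF and tabular I/O.

Reads per-study VCFs into (raw variant, study observation) pairs — one per
ALT allele — collecting per-subpopulation allele counts (AC), allele numbers
(AN) and frequencies (AF) from INFO fields, and the FILTER-derived pass
flag. Writes key-annotated copies of input VCFs, and exports registry
records as TSV or JSON.

Subpopulation INFO naming follows the ``AC_<POP>/AN_<POP>/AF_<POP>`` dialect
by default; a per-study field map handles other dialects (e.g. cohort files
that carry only ``EAS_AF``-style frequencies). The overall cohort counts
(plain ``AC``/``AN``/``AF``) are kept under the subpopulation label ``ALL``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional

import pysam

from .errors import VcfParseError
from .normalize import RawVariant

logger = logging.getLogger(__name__)

__all__ = ["StudyObservation", "read_study_vcf", "write_keyed_vcf", "export"]

#: label under which a study's overall (non-subpopulation) counts are kept.
OVERALL = "ALL"

#: frozen TSV column order for exports.
EXPORT_COLUMNS = (
    "variant_key",
    "chrom",
    "start",
    "end",
    "ref",
    "alt",
    "vtype",
    "effective_size",
    "dbsnp_id",
    "sources",
    "max_af",
)


@dataclass
class StudyObservation:
    """One study's evidence for one alternate allele.

    ``counts`` maps subpopulation label → (AC, AN); ``af`` maps label →
    allele frequency. When a file carries AF without AC/AN the frequency is
    kept and the counts entry is absent. ``passed`` is True iff at least one
    contributing record passed the study's filters (FILTER is PASS or '.').
    """

    study_id: str
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    af: dict[str, float] = field(default_factory=dict)
    passed: bool = False


def _scalar(value, index: int):
    """Pick the per-ALT element from an INFO value (Number=A tuple or scalar)."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        if index < len(value):
            return value[index]
        return value[0] if value else None
    return value


def _default_field_map(header) -> dict[str, tuple[Optional[str], Optional[str], Optional[str]]]:
    """Infer subpopulation INFO keys following the AC_/AN_/AF_ dialect."""
    keys = set(header.info.keys())
    pops = set()
    for k in keys:
        for prefix in ("AC_", "AN_", "AF_"):
            if k.startswith(prefix):
                pops.add(k[len(prefix) :])
    fmap: dict[str, tuple[Optional[str], Optional[str], Optional[str]]] = {}
    for pop in sorted(pops):
        fmap[pop] = (
            f"AC_{pop}" if f"AC_{pop}" in keys else None,
            f"AN_{pop}" if f"AN_{pop}" in keys else None,
            f"AF_{pop}" if f"AF_{pop}" in keys else None,
        )
    fmap[OVERALL] = (
        "AC" if "AC" in keys else None,
        "AN" if "AN" in keys else None,
        "AF" if "AF" in keys else None,
    )
    return fmap


def read_study_vcf(
    path: str,
    study_id: str,
    subpop_field_map: Optional[dict] = None,
) -> Iterator[tuple[RawVariant, StudyObservation]]:
    """Stream (RawVariant, StudyObservation) pairs from a study VCF.

    Multi-allelic records are decomposed into one pair per ALT allele.
    ``subpop_field_map`` maps subpopulation label → (AC key, AN key, AF key)
    in INFO (entries may be None); when omitted, keys are inferred from the
    header following the ``AC_<POP>`` dialect. FILTER '.' (missing) counts
    as pass, per common practice with sites files; this is logged once.
    """
    with pysam.VariantFile(path) as vcf:
        fmap = subpop_field_map or _default_field_map(vcf.header)
        dot_logged = False
        for rec in vcf:
            try:
                filters = list(rec.filter.keys())
                passed = (not filters) or ("PASS" in filters)
                if not filters and not dot_logged:
                    logger.info("%s: FILTER '.' treated as pass", path)
                    dot_logged = True
                alts = rec.alts or ()
                for i, alt in enumerate(alts):
                    obs = StudyObservation(study_id=study_id, passed=passed)
                    for pop, (ack, ank, afk) in fmap.items():
                        ac = _scalar(rec.info.get(ack), i) if ack else None
                        an = _scalar(rec.info.get(ank), i) if ank else None
                        af = _scalar(rec.info.get(afk), i) if afk else None
                        if ac is not None and an is not None:
                            obs.counts[pop] = (int(ac), int(an))
                            if an:
                                obs.af[pop] = int(ac) / int(an)
                        if af is not None and pop not in obs.af:
                            obs.af[pop] = float(af)
                    if not obs.counts and not obs.af:
                        logger.warning(
                            "%s:%s no AC/AN/AF INFO found for %s; observation "
                            "retained with empty counts",
                            path,
                            rec.pos,
                            study_id,
                        )
                    yield (
                        RawVariant(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt),
                        obs,
                    )
            except (ValueError, TypeError) as exc:
                raise VcfParseError(
                    f"{path}: failed to parse record at {rec.chrom}:{rec.pos}: {exc}"
                ) from exc


KEY_TAG = "VKEY"
_KEY_HEADER = (
    f'##INFO=<ID={KEY_TAG},Number=A,Type=String,'
    f'Description="Reversible sortable variant key (one per ALT allele)">'
)


def write_keyed_vcf(
    in_path: str,
    out_path: str,
    reference,
    build_code: int = 37,
) -> int:
    """Copy a VCF, annotating each ALT allele with its variant key.

    Adds one INFO header line and a per-ALT ``VKEY`` tag; all other content
    is preserved. Alleles that cannot be normalized (symbolic ALTs,
    reference mismatches) are tagged '.' and logged, not fatal. Re-running
    on already-annotated output replaces rather than duplicates the tag.
    Returns the number of annotated records.
    """
    from .keycodec import encode_key
    from .normalize import left_align

    with pysam.VariantFile(in_path) as vin:
        header = vin.header.copy()
        if KEY_TAG not in header.info:
            header.add_line(_KEY_HEADER)
        count = 0
        with pysam.VariantFile(out_path, "w", header=header) as vout:
            for rec in vin:
                keys = []
                for alt in rec.alts or ():
                    try:
                        norm = left_align(
                            RawVariant(rec.chrom, rec.pos, rec.ref, alt),
                            reference,
                            build_code=build_code,
                        )
                        keys.append(encode_key(norm).text)
                    except Exception as exc:  # symbolic ALT, mismatch, ...
                        logger.warning(
                            "%s:%s ALT %s not keyable: %s", rec.chrom, rec.pos, alt, exc
                        )
                        keys.append(".")
                out = rec.copy()
                out.translate(header)
                if keys:
                    out.info[KEY_TAG] = tuple(keys)
                    count += 1
                vout.write(out)
    return count


def _record_dict(record) -> dict:
    """Flatten a registry record (duck-typed) for export."""
    v = record.variant
    return {
        "variant_key": record.variant_key,
        "chrom": v.chrom,
        "start": v.start,
        "end": v.end,
        "ref": v.ref,
        "alt": v.alt,
        "vtype": v.vtype,
        "effective_size": v.effective_size,
        "dbsnp_id": record.dbsnp_id or "",
        "sources": ",".join(sorted(record.sources)),
        "max_af": record.max_af if record.max_af is not None else "",
    }


#: version tag written into every JSON export envelope.
JSON_SCHEMA_VERSION = "1.0"


def export(records, format: str, path: str) -> None:
    """Write registry records as TSV (frozen column order) or JSON.

    The JSON document is an envelope ``{"schema_version", "records"}`` where
    each record nests its annotations by category (impact, frequencies,
    phenotype, region) next to the flat summary fields.
    """
    records = list(records)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(EXPORT_COLUMNS) + "\n")
            for rec in records:
                d = _record_dict(rec)
                fh.write("\t".join(str(d[c]) for c in EXPORT_COLUMNS) + "\n")
    elif format == "json":
        def freq_dict(rec) -> dict:
            out = {}
            for key, val in (getattr(rec, "frequencies", {}) or {}).items():
                study, pop = key if isinstance(key, tuple) else (key, "ALL")
                out.setdefault(study, {})[pop] = val
            return out

        payload = {
            "schema_version": JSON_SCHEMA_VERSION,
            "records": [
                {
                    **_record_dict(rec),
                    "annotations": getattr(rec, "annotations", {}) or {},
                    "frequencies": freq_dict(rec),
                }
                for rec in records
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unknown export format: {format!r}")
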