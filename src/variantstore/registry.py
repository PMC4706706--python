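"""Single-file embedded variant registry (SQLite).

Implements the staging → production workflow: observations from study VCFs
are staged, partitioned into known vs. novel against the production store,
and registered — novel variants immediately get a minimal summary row
(type, effective size, variant key) and become queryable, while every
observation attaches a per-study source row, pass flag and subpopulation
allele counts. Imported annotation tables (impact, predictions, phenotypes,
clinical assertions, regions) attach to existing records or create
annotation-only records for variants never observed in a study.

Identity is one record per (build, chromosome, start, end, alt allele); the
variant-key column carries a non-unique index because keys of very long
insertions are truncated and may collide — such records are disambiguated
by allele, while a genuine overwrite of a *unique* key by a different
allele raises :class:`~variantstore.errors.KeyCollisionError`.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .errors import (
    KeyCollisionError,
    ReferenceMismatchError,
    UnknownStudyError,
)
from .keycodec import decode_key, encode_key, range_prefix
from .normalize import NormalizedVariant, RawVariant, left_align

__all__ = ["Registry", "RegistryRecord", "ClinicalAssertion", "StagingBatch",
           "SIGNIFICANCE_LABELS"]

#: closed clinical-significance vocabulary.
SIGNIFICANCE_LABELS = (
    "pathogenic",
    "likely_pathogenic",
    "risk_factor",
    "association",
    "likely_benign",
    "benign",
    "protective",
    "drug_response",
    "VUS",
    "other",
    "unknown",
)

ANNOTATION_CATEGORIES = ("impact", "prediction", "phenotype", "region", "clinical")


@dataclass(frozen=True)
class ClinicalAssertion:
    """A curated significance label attached to a variant by a source."""

    source: str
    significance: str

    def __post_init__(self):
        if self.significance not in SIGNIFICANCE_LABELS:
            raise ValueError(
                f"significance {self.significance!r} outside the closed vocabulary"
            )


@dataclass
class RegistryRecord:
    """Production-store row: variant + key + sources + annotations."""

    variant_key: str
    variant: NormalizedVariant
    dbsnp_id: Optional[str] = None
    sources: dict[str, bool] = field(default_factory=dict)  # study_id -> passed
    annotations: dict[str, list] = field(default_factory=dict)  # category -> rows
    frequencies: dict = field(default_factory=dict)  # (study, subpop) -> af
    max_af: Optional[float] = None


@dataclass
class StagingBatch:
    """A staged ingestion batch, partitioned against the production store."""

    known: list  # (NormalizedVariant, key_text, StudyObservation)
    novel: list

    def __iter__(self):
        return iter(self.known + self.novel)


_SCHEMA = """
CREATE TABLE IF NOT EXISTS variants (
    id INTEGER PRIMARY KEY,
    vkey TEXT NOT NULL,
    key_unique INTEGER NOT NULL,
    build INTEGER NOT NULL,
    chrom TEXT NOT NULL,
    chrom_code INTEGER NOT NULL,
    start INTEGER NOT NULL,
    end INTEGER NOT NULL,
    ref TEXT,
    alt TEXT,
    vtype TEXT,
    effective_size INTEGER,
    dbsnp_id TEXT,
    UNIQUE (build, chrom_code, start, end, alt)
);
CREATE INDEX IF NOT EXISTS idx_variants_vkey ON variants (vkey);
CREATE INDEX IF NOT EXISTS idx_variants_loc ON variants (chrom_code, start);
CREATE TABLE IF NOT EXISTS sources (
    variant_id INTEGER NOT NULL REFERENCES variants (id),
    study_id TEXT NOT NULL,
    passed INTEGER NOT NULL,
    UNIQUE (variant_id, study_id)
);
CREATE TABLE IF NOT EXISTS observations (
    variant_id INTEGER NOT NULL REFERENCES variants (id),
    study_id TEXT NOT NULL,
    subpop TEXT NOT NULL,
    ac INTEGER,
    an INTEGER,
    af REAL,
    UNIQUE (variant_id, study_id, subpop)
);
CREATE TABLE IF NOT EXISTS annotations (
    variant_id INTEGER NOT NULL REFERENCES variants (id),
    category TEXT NOT NULL,
    source TEXT NOT NULL,
    label TEXT NOT NULL,
    UNIQUE (variant_id, category, source, label)
);
"""


class Registry:
    """The embedded variant store.

    Parameters
    ----------
    path:
        SQLite file path, or ":memory:" for an in-process store.
    reference:
        Reference-sequence accessor (mapping or pyfaidx Fasta) used to
        normalize raw variants on ingestion and annotation import.
    build_code:
        GRCh build number stamped into keys (default 37).
    """

    def __init__(self, path: str = ":memory:", reference=None, build_code: int = 37):
        self.conn = sqlite3.connect(path)
        self.conn.executescript(_SCHEMA)
        self.reference = reference
        self.build_code = build_code

    def close(self):
        self.conn.close()

    # -- staging / registration -------------------------------------------

    def _normalize(self, variant) -> NormalizedVariant:
        if isinstance(variant, NormalizedVariant):
            return variant
        if isinstance(variant, RawVariant):
            if self.reference is None:
                raise ReferenceMismatchError(
                    "a reference is required to normalize raw variants"
                )
            return left_align(variant, self.reference, build_code=self.build_code)
        raise TypeError(f"cannot normalize {type(variant).__name__}")

    def _find_id(self, v: NormalizedVariant) -> Optional[int]:
        row = self.conn.execute(
            "SELECT id FROM variants WHERE build=? AND chrom_code=? AND start=? "
            "AND end=? AND alt=?",
            (v.build_code, v.chrom_code, v.start, v.end, v.alt),
        ).fetchone()
        return row[0] if row else None

    def stage(
        self, observations: Iterable[tuple]
    ) -> StagingBatch:
        """Partition observations into known and novel variants.

        ``observations`` yields (RawVariant | NormalizedVariant,
        StudyObservation) pairs, e.g. from
        :func:`variantstore.vcf_io.read_study_vcf`. Spellings that normalize
        to the same canonical variant are merged within the batch.
        """
        known, novel = [], []
        seen_in_batch: dict[tuple, int] = {}
        merged: list = []
        for variant, obs in observations:
            norm = self._normalize(variant)
            ident = norm.identity
            if ident in seen_in_batch:
                prev = merged[seen_in_batch[ident]]
                prev[2].passed = prev[2].passed or obs.passed
                for pop, c in obs.counts.items():
                    prev[2].counts.setdefault(pop, c)
                for pop, f in obs.af.items():
                    prev[2].af.setdefault(pop, f)
                continue
            key = encode_key(norm)
            seen_in_batch[ident] = len(merged)
            merged.append((norm, key.text, obs))
        for item in merged:
            (known if self._find_id(item[0]) is not None else novel).append(item)
        return StagingBatch(known=known, novel=novel)

    def register(self, batch: StagingBatch) -> dict:
        """Move a staged batch into the production store.

        Novel variants get a summary row right away (minimal information:
        coordinates, alleles, type, effective size, key); source rows,
        pass flags and subpopulation counts are attached for every item.
        Re-registration of a known variant is a no-op for the summary row.
        Returns ``{"novel_registered": n, "sources_attached": m}``.
        """
        cur = self.conn.cursor()
        novel_registered = 0
        sources_attached = 0
        for norm, key_text, obs in batch:
            vid = self._find_id(norm)
            if vid is None:
                clash = cur.execute(
                    "SELECT id, alt, key_unique FROM variants WHERE vkey=?",
                    (key_text,),
                ).fetchone()
                from .keycodec import MAX_UNIQUE_ALT_LEN

                if clash is not None and len(norm.alt or "") <= MAX_UNIQUE_ALT_LEN \
                        and clash[2]:
                    raise KeyCollisionError(
                        f"unique key {key_text[:20]}... already maps to a "
                        f"different allele"
                    )
                unique = int(len(norm.alt or "") <= MAX_UNIQUE_ALT_LEN
                             and set(norm.alt or "") <= set("ACGT"))
                cur.execute(
                    "INSERT INTO variants (vkey, key_unique, build, chrom, "
                    "chrom_code, start, end, ref, alt, vtype, effective_size) "
                    "VALUES (?,?,?,?,?,?,?,?,?,?,?)",
                    (
                        key_text,
                        unique,
                        norm.build_code,
                        norm.chrom,
                        norm.chrom_code,
                        norm.start,
                        norm.end,
                        norm.ref,
                        norm.alt,
                        norm.vtype,
                        norm.effective_size,
                    ),
                )
                vid = cur.lastrowid
                novel_registered += 1
            if obs is None:
                continue
            prev = cur.execute(
                "SELECT passed FROM sources WHERE variant_id=? AND study_id=?",
                (vid, obs.study_id),
            ).fetchone()
            if prev is None:
                cur.execute(
                    "INSERT INTO sources (variant_id, study_id, passed) VALUES (?,?,?)",
                    (vid, obs.study_id, int(obs.passed)),
                )
                sources_attached += 1
            elif obs.passed and not prev[0]:
                cur.execute(
                    "UPDATE sources SET passed=1 WHERE variant_id=? AND study_id=?",
                    (vid, obs.study_id),
                )
            pops = set(obs.counts) | set(obs.af)
            for pop in pops:
                ac, an = obs.counts.get(pop, (None, None))
                af = obs.af.get(pop)
                if af is None and ac is not None and an:
                    af = ac / an
                cur.execute(
                    "INSERT OR IGNORE INTO observations "
                    "(variant_id, study_id, subpop, ac, an, af) VALUES (?,?,?,?,?,?)",
                    (vid, obs.study_id, pop, ac, an, af),
                )
        self.conn.commit()
        return {
            "novel_registered": novel_registered,
            "sources_attached": sources_attached,
        }

    def ingest(self, observations: Iterable[tuple]) -> dict:
        """stage + register in one call."""
        return self.register(self.stage(observations))

    def finalize(self) -> None:
        """Commit and refresh query-planner statistics (on-demand update)."""
        self.conn.commit()
        self.conn.execute("ANALYZE")

    # -- annotations --------------------------------------------------------

    def import_annotations(self, table, category: str) -> int:
        """Attach an imported annotation table to the store.

        ``table`` is a pandas DataFrame (or list of dicts) whose rows are
        keyed either by ``variant_key`` or by (``chrom``, ``pos``, ``ref``,
        ``alt``) — the latter are normalized on import. Required columns:
        ``source`` and ``label`` (for ``category="clinical"``, the label is
        the significance and must come from the closed vocabulary).
        Unmatched rows create annotation-only records with no sources.
        Re-import is idempotent. Returns the number of attached rows.
        """
        if category not in ANNOTATION_CATEGORIES:
            raise ValueError(f"unknown annotation category {category!r}")
        if isinstance(table, pd.DataFrame):
            rows = table.to_dict("records")
        else:
            rows = list(table)
        cur = self.conn.cursor()
        attached = 0
        for row in rows:
            if category == "clinical":
                ClinicalAssertion(row["source"], row["label"])  # vocabulary check
            if row.get("variant_key"):
                norm = decode_key(row["variant_key"], self.reference)
            else:
                raw = RawVariant(
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    ref=str(row["ref"]),
                    alt=str(row["alt"]),
                )
                norm = left_align(raw, self.reference, build_code=self.build_code)
            vid = self._find_id(norm)
            if vid is None:
                self.register(StagingBatch(known=[], novel=[
                    (norm, encode_key(norm).text, None)
                ]))
                vid = self._find_id(norm)
            cur.execute(
                "INSERT OR IGNORE INTO annotations (variant_id, category, source, "
                "label) VALUES (?,?,?,?)",
                (vid, category, str(row["source"]), str(row["label"])),
            )
            attached += cur.rowcount
            if row.get("dbsnp_id"):
                cur.execute(
                    "UPDATE variants SET dbsnp_id=? WHERE id=? AND dbsnp_id IS NULL",
                    (str(row["dbsnp_id"]), vid),
                )
        self.conn.commit()
        return attached

    # -- reporting ----------------------------------------------------------

    def study_ids(self) -> list[str]:
        return [
            r[0]
            for r in self.conn.execute(
                "SELECT DISTINCT study_id FROM sources ORDER BY study_id"
            )
        ]

    def novelty_report(self) -> pd.DataFrame:
        """Per-study counts: variants, unique_to_study, passed.

        ``unique_to_study`` counts variants observed only in that study;
        ``passed`` counts variants whose per-study pass flag is set.
        """
        df = pd.read_sql_query(
            "SELECT s.study_id, s.variant_id, s.passed, "
            " (SELECT COUNT(*) FROM sources s2 WHERE s2.variant_id = s.variant_id)"
            " AS n_sources FROM sources s",
            self.conn,
        )
        if df.empty:
            return pd.DataFrame(
                columns=["variants", "unique_to_study", "passed"]
            ).rename_axis("study_id")
        out = df.groupby("study_id").agg(
            variants=("variant_id", "size"),
            unique_to_study=("n_sources", lambda s: int((s == 1).sum())),
            passed=("passed", "sum"),
        )
        return out

    # -- queries ------------------------------------------------------------

    def _record_from_row(self, row) -> RegistryRecord:
        (vid, vkey, key_unique, build, chrom, chrom_code, start, end, ref, alt,
         vtype, eff, dbsnp) = row
        variant = NormalizedVariant(
            build_code=build, chrom=chrom, chrom_code=chrom_code, start=start,
            end=end, ref=ref, alt=alt, vtype=vtype, effective_size=eff,
        )
        rec = RegistryRecord(variant_key=vkey, variant=variant, dbsnp_id=dbsnp)
        for study, passed in self.conn.execute(
            "SELECT study_id, passed FROM sources WHERE variant_id=?", (vid,)
        ):
            rec.sources[study] = bool(passed)
        for study, pop, ac, an, af in self.conn.execute(
            "SELECT study_id, subpop, ac, an, af FROM observations "
            "WHERE variant_id=?",
            (vid,),
        ):
            rec.frequencies[(study, pop)] = {"ac": ac, "an": an, "af": af}
        for cat, source, label in self.conn.execute(
            "SELECT category, source, label FROM annotations WHERE variant_id=?",
            (vid,),
        ):
            rec.annotations.setdefault(cat, []).append(
                {"source": source, "label": label}
            )
        afs = [f["af"] for f in rec.frequencies.values() if f["af"] is not None]
        rec.max_af = max(afs) if afs else None
        return rec

    _SELECT = (
        "SELECT id, vkey, key_unique, build, chrom, chrom_code, start, end, "
        "ref, alt, vtype, effective_size, dbsnp_id FROM variants "
    )

    def query_by_key(self, key_text: str) -> list[RegistryRecord]:
        rows = self.conn.execute(
            self._SELECT + "WHERE vkey=? ORDER BY id", (key_text,)
        ).fetchall()
        return [self._record_from_row(r) for r in rows]

    def query_by_dbsnp(self, dbsnp_id: str) -> list[RegistryRecord]:
        rows = self.conn.execute(
            self._SELECT + "WHERE dbsnp_id=? ORDER BY id", (dbsnp_id,)
        ).fetchall()
        return [self._record_from_row(r) for r in rows]

    def query_by_location(
        self, chrom_code: int, start_lo: int, start_hi: Optional[int] = None
    ) -> list[RegistryRecord]:
        if start_hi is None:
            start_hi = start_lo
        rows = self.conn.execute(
            self._SELECT + "WHERE chrom_code=? AND start BETWEEN ? AND ? "
            "ORDER BY start, id",
            (chrom_code, start_lo, start_hi),
        ).fetchall()
        return [self._record_from_row(r) for r in rows]

    def query_range_prefix(
        self, chrom_code: int, start_lo: int, start_hi: int,
        build: Optional[int] = None,
    ) -> list[RegistryRecord]:
        """Range scan over the byte-sorted key index via key-string bounds."""
        lo, hi = range_prefix(
            self.build_code if build is None else build, chrom_code,
            start_lo, start_hi,
        )
        rows = self.conn.execute(
            self._SELECT + "WHERE vkey BETWEEN ? AND ? ORDER BY vkey, id", (lo, hi)
        ).fetchall()
        return [self._record_from_row(r) for r in rows]

    def all_records(self) -> list[RegistryRecord]:
        rows = self.conn.execute(self._SELECT + "ORDER BY vkey, id").fetchall()
        return [self._record_from_row(r) for r in rows]

    def assert_studies_known(self, studies: Iterable[str]) -> None:
        known = set(self.study_ids())
        unknown = set(studies) - known
        if unknown:
            raise UnknownStudyError(f"unknown studies: {sorted(unknown)}")
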