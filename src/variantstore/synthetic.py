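"""Deterministic synthetic-data generator.

Emulates, at toy scale, the inputs a multi-study variant store ingests: a
reference genome with repeat tracts (homopolymers and dinucleotide repeats,
to exercise left-alignment), per-study cohort VCFs with subpopulation
allele counts (AC/AN/AF consistent by construction), planted clinical
assertion tables including contradictory pathogenicity pairs, and
deliberately non-left-aligned variant spellings. Every generated file is a
pure function of the :class:`SimDesign` (one pseudo-random stream per
design seed), so regeneration is bit-reproducible and every planted fact is
recorded in a truth table for oracle tests.

What this emulates — and what it does not: subpopulation-structured allele
frequencies, cross-study sharing, quality-filter failures and redundant
variant spellings are all present; linkage, genotype-level data, sequencing
error and annotation noise are not, so tests against the truth table
exercise bookkeeping and statistics, not variant calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .keycodec import encode_key
from .normalize import NormalizedVariant, RawVariant, left_align

__all__ = [
    "StudyDesign",
    "SimDesign",
    "SimResult",
    "TruthVariant",
    "simulate",
    "make_reference",
    "make_study_vcf",
    "make_clinical_table",
]

BASES = "ACGT"


@dataclass(frozen=True)
class StudyDesign:
    """One study: cohort size, subpopulation shares, role, variant load."""

    study_id: str
    n_samples: int
    subpops: tuple  # of (label, share); shares sum to 1
    role: str = "healthy"
    n_background: int = 120

    def __post_init__(self):
        total = sum(s for _, s in self.subpops)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subpopulation shares must sum to 1, got {total}")


def _default_studies() -> tuple:
    return (
        StudyDesign("STUDY_A", 200, (("EUR", 0.5), ("AFR", 0.3), ("EAS", 0.2)),
                    "healthy", 120),
        StudyDesign("STUDY_B", 150, (("EUR", 0.6), ("SAS", 0.4)), "healthy", 100),
        StudyDesign("STUDY_C", 100, (("EUR", 1.0),), "healthy", 80),
        StudyDesign("DISEASE_D", 50, (("EUR", 1.0),), "disease", 60),
    )


@dataclass(frozen=True)
class SimDesign:
    """Parameters of one synthetic multi-study cohort.

    Defaults are the toy scale used throughout the test-suite: two 100 kb
    contigs, three healthy studies plus one disease study of 50–200
    background variants each, an allele-frequency spectrum dominated by
    rare variation, 30% cross-study sharing, 25% denormalized spellings and
    10% quality-filter failures.
    """

    seed: int = 0
    contigs: tuple = (("1", 100_000), ("2", 100_000))
    gc: float = 0.41
    repeat_every: int = 5_000
    studies: tuple = field(default_factory=_default_studies)
    #: weights of the background AF spectrum (common, low-frequency, rare)
    af_weights: tuple = (0.15, 0.30, 0.55)
    share_prob: float = 0.30
    denormalized_fraction: float = 0.25
    filter_fail_fraction: float = 0.10
    n_pathogenic_common: int = 5
    n_benign_common: int = 5
    n_contradictory: int = 4
    n_disease_private: int = 8
    n_long_insertions: int = 2
    n_clinical_only: int = 6
    n_multiallelic: int = 4
    n_duplicate_spellings: int = 3
    n_assorted_assertions: int = 15
    clinical_sources: tuple = ("CLINDB", "MUTDB")
    build_code: int = 37


@dataclass
class StudyTruth:
    """Planted per-study evidence for one variant."""

    counts: dict  # subpop label -> (ac, an); includes "ALL"
    passed: bool


@dataclass
class TruthVariant:
    """One planted variant with its canonical form, key and evidence."""

    variant: NormalizedVariant
    key: str
    category: str
    studies: dict = field(default_factory=dict)  # study_id -> StudyTruth
    assertions: list = field(default_factory=list)  # (source, significance)

    def max_af(self, study_ids) -> float:
        best = 0.0
        for sid in study_ids:
            st = self.studies.get(sid)
            if st is None:
                continue
            for ac, an in st.counts.values():
                if an:
                    best = max(best, ac / an)
        return best


@dataclass
class SimResult:
    """All generated artifacts plus the truth table."""

    design: SimDesign
    reference: dict  # contig name -> sequence
    reference_path: Optional[str]
    vcf_paths: dict  # study_id -> path
    clinical_path: Optional[str]
    truth: dict  # identity tuple -> TruthVariant

    # -- truth-table accessors used as test oracles ------------------------

    def variants_of(self, study_id: str) -> list[TruthVariant]:
        return [t for t in self.truth.values() if study_id in t.studies]

    def keys_in_category(self, category: str) -> set[str]:
        return {t.key for t in self.truth.values() if t.category == category}

    def novelty_truth(self):
        import pandas as pd

        rows = {}
        for sd in self.design.studies:
            mine = self.variants_of(sd.study_id)
            rows[sd.study_id] = {
                "variants": len(mine),
                "unique_to_study": sum(1 for t in mine if len(t.studies) == 1),
                "passed": sum(1 for t in mine if t.studies[sd.study_id].passed),
            }
        return pd.DataFrame.from_dict(rows, orient="index").rename_axis("study_id")

    @property
    def healthy_study_ids(self) -> list[str]:
        return [s.study_id for s in self.design.studies if s.role == "healthy"]

    @property
    def disease_study_ids(self) -> list[str]:
        return [s.study_id for s in self.design.studies if s.role == "disease"]


# -- reference ------------------------------------------------------------


def _make_contig(rng: np.random.Generator, length: int, gc: float,
                 repeat_every: int) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(list(BASES), size=length, p=p)
    # implant repeat tracts to exercise left-alignment
    pos = repeat_every
    while pos + 40 < length:
        if rng.random() < 0.5:
            base = BASES[rng.integers(4)]
            run = int(rng.integers(8, 16))
            seq[pos : pos + run] = base
        else:
            a, b = rng.choice(list(BASES), size=2, replace=False)
            units = int(rng.integers(6, 11))
            tract = (a + b) * units
            seq[pos : pos + len(tract)] = list(tract)
        pos += repeat_every
    return "".join(seq)


def _build_reference(design: SimDesign, rng: np.random.Generator) -> dict:
    return {
        name: _make_contig(rng, length, design.gc, design.repeat_every)
        for name, length in design.contigs
    }


def make_reference(design: SimDesign, path: str) -> str:
    """Write the design's reference as an indexed FASTA (bit-reproducible)."""
    rng = np.random.default_rng(design.seed)
    reference = _build_reference(design, rng)
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    import pyfaidx

    pyfaidx.Faidx(path)  # create .fai alongside
    return path


# -- variant pool ---------------------------------------------------------


def _random_variant(
    rng: np.random.Generator, reference: dict, contig: str, pos: int,
    kind: str, build: int, alt_len: Optional[int] = None,
) -> NormalizedVariant:
    """Construct a candidate edit and canonicalize it via left_align."""
    seq = reference[contig]
    refbase = seq[pos - 1]
    if kind == "SNV":
        alt = BASES[(BASES.index(refbase) + int(rng.integers(1, 4))) % 4]
        raw = RawVariant(contig, pos, refbase, alt)
    elif kind == "INS":
        n = alt_len if alt_len is not None else int(rng.integers(1, 9))
        ins = "".join(BASES[i] for i in rng.integers(0, 4, size=n))
        raw = RawVariant(contig, pos, refbase, refbase + ins)
    elif kind == "DEL":
        n = int(rng.integers(1, 9))
        raw = RawVariant(contig, pos, seq[pos - 1 : pos + n], refbase)
    else:  # MNV
        n = int(rng.integers(2, 4))
        ref = seq[pos - 1 : pos - 1 + n]
        alt = "".join(
            BASES[(BASES.index(b) + int(rng.integers(1, 4))) % 4] for b in ref
        )
        raw = RawVariant(contig, pos, ref, alt)
    return left_align(raw, reference, build_code=build)


def _plant_variants(design: SimDesign, rng: np.random.Generator,
                    reference: dict) -> dict:
    """Build the full truth table: variants, assignments, counts, labels."""
    truth: dict = {}
    contig_names = [c for c, _ in design.contigs]
    healthy = [s for s in design.studies if s.role == "healthy"]
    disease = [s for s in design.studies if s.role == "disease"]

    def an_for(study: StudyDesign) -> dict:
        out = {}
        for pop, share in study.subpops:
            out[pop] = 2 * int(round(study.n_samples * share))
        return out

    def observe(tv: TruthVariant, study: StudyDesign, af: float,
                passed: bool = True):
        counts = {}
        total_ac = total_an = 0
        for pop, an in an_for(study).items():
            # jitter the subpopulation AF around the planted value
            f = max(0.0, af * float(rng.uniform(0.5, 1.5)))
            ac = min(an, max(1, int(round(f * an))) if af > 0 else 0)
            counts[pop] = (ac, an)
            total_ac += ac
            total_an += an
        counts["ALL"] = (total_ac, total_an)
        tv.studies[study.study_id] = StudyTruth(counts=counts, passed=passed)

    def new_variant(category: str, kind: Optional[str] = None,
                    alt_len: Optional[int] = None) -> TruthVariant:
        for _ in range(200):
            contig = contig_names[int(rng.integers(len(contig_names)))]
            length = len(reference[contig])
            pos = int(rng.integers(100, length - 3200))
            k = kind or rng.choice(
                ["SNV", "INS", "DEL", "MNV"], p=[0.70, 0.12, 0.12, 0.06]
            )
            try:
                norm = _random_variant(
                    rng, reference, contig, pos, str(k), design.build_code,
                    alt_len=alt_len,
                )
            except Exception:
                continue
            ident = norm.identity
            # keep variants well separated so spellings never interact
            near = any(
                abs(norm.start - other.variant.start) < 40
                and norm.chrom == other.variant.chrom
                for other in truth.values()
            )
            if ident in truth or near:
                continue
            tv = TruthVariant(variant=norm, key=encode_key(norm).text,
                              category=category)
            truth[ident] = tv
            return tv
        raise RuntimeError("could not place a variant; contigs too crowded")

    def af_draw(category: str) -> float:
        if category == "common":
            return float(rng.uniform(0.05, 0.5))
        if category == "low":
            return float(rng.uniform(0.005, 0.05))
        return float(rng.uniform(0.0005, 0.005))

    # planted pathogenic-but-common variants (seen in every healthy study)
    for _ in range(design.n_pathogenic_common):
        tv = new_variant("pathogenic_common", kind="SNV")
        af = float(rng.uniform(0.02, 0.2))
        for s in healthy:
            observe(tv, s, af)
        tv.assertions.append((design.clinical_sources[0], "pathogenic"))

    for _ in range(design.n_benign_common):
        tv = new_variant("benign_common", kind="SNV")
        af = float(rng.uniform(0.1, 0.5))
        for s in healthy:
            observe(tv, s, af)
        tv.assertions.append((design.clinical_sources[0], "benign"))

    # contradictory assertions within one source → excluded from bin tables
    for _ in range(design.n_contradictory):
        tv = new_variant("contradictory", kind="SNV")
        observe(tv, healthy[int(rng.integers(len(healthy)))], af_draw("low"))
        src = design.clinical_sources[0]
        tv.assertions.append((src, "pathogenic"))
        tv.assertions.append((src, "benign"))

    # disease-private variants: carriers only in disease studies
    for _ in range(design.n_disease_private):
        tv = new_variant("disease_private")
        for s in disease:
            observe(tv, s, float(rng.uniform(0.01, 0.1)))

    # insertions beyond the lossless key limit (truncated, non-unique keys)
    for _ in range(design.n_long_insertions):
        n = int(rng.integers(2959, 3100))
        tv = new_variant("long_insertion", kind="INS", alt_len=n)
        observe(tv, healthy[0], af_draw("rare"))

    # background spectrum per study, with cross-study sharing
    spectrum = ["common", "low", "rare"]
    for s in healthy + disease:
        for _ in range(s.n_background):
            cat = str(rng.choice(spectrum, p=list(design.af_weights)))
            tv = new_variant("background")
            af = af_draw(cat)
            passed = bool(rng.random() >= design.filter_fail_fraction)
            observe(tv, s, af, passed=passed)
            if s.role == "healthy" and len(healthy) > 1 \
                    and rng.random() < design.share_prob:
                others = [o for o in healthy if o.study_id != s.study_id]
                other = others[int(rng.integers(len(others)))]
                observe(tv, other, af_draw(cat),
                        passed=bool(rng.random() >= design.filter_fail_fraction))

    # multi-allelic sites: a second SNV allele at an existing SNV position
    snv_idents = [
        i for i, t in truth.items()
        if t.variant.vtype == "SNV" and t.category == "background" and t.studies
    ]
    for idx in rng.choice(len(snv_idents), size=min(design.n_multiallelic,
                                                    len(snv_idents)),
                          replace=False):
        first = truth[snv_idents[int(idx)]]
        v = first.variant
        taken = {v.alt, v.ref}
        alt2 = next(b for b in BASES if b not in taken)
        norm = NormalizedVariant(
            build_code=v.build_code, chrom=v.chrom, chrom_code=v.chrom_code,
            start=v.start, end=v.end, ref=v.ref, alt=alt2, vtype="SNV",
            effective_size=0,
        )
        if norm.identity in truth:
            continue
        tv = TruthVariant(variant=norm, key=encode_key(norm).text,
                          category="multiallelic")
        sid = next(iter(first.studies))
        study = next(s for s in design.studies if s.study_id == sid)
        observe(tv, study, af_draw("rare"),
                passed=first.studies[sid].passed)
        truth[norm.identity] = tv

    # clinically asserted but never observed in any study
    for _ in range(design.n_clinical_only):
        tv = new_variant("clinical_only")
        tv.assertions.append(
            (design.clinical_sources[0],
             str(rng.choice(["VUS", "unknown", "likely_pathogenic"])))
        )

    # assorted assertions scattered over observed background variants
    bg = [t for t in truth.values()
          if t.category == "background" and not t.assertions]
    labels = ["pathogenic", "likely_pathogenic", "risk_factor", "likely_benign",
              "benign", "VUS", "other", "unknown"]
    take = rng.choice(len(bg), size=min(design.n_assorted_assertions, len(bg)),
                      replace=False)
    for i, idx in enumerate(take):
        src = design.clinical_sources[i % len(design.clinical_sources)]
        bg[int(idx)].assertions.append(
            (src, str(rng.choice(labels)))
        )
    return truth


# -- VCF writing ----------------------------------------------------------

_VCF_INFO_HEADER = [
    '##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count">',
    '##INFO=<ID=AN,Number=1,Type=Integer,Description="Total allele number">',
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">',
]


def _denormalize(rng: np.random.Generator, reference: dict,
                 v: NormalizedVariant) -> tuple:
    """An equivalent, non-canonical spelling: add shared flanking context."""
    seq = reference[v.chrom]
    pos, ref, alt = v.start, v.ref, v.alt
    k_pre = int(rng.integers(0, 3))
    k_post = int(rng.integers(0, 3))
    if k_pre == 0 and k_post == 0:
        k_pre = 1
    pre = seq[pos - 1 - k_pre : pos - 1]
    post = seq[pos - 1 + len(ref) : pos - 1 + len(ref) + k_post]
    return pos - len(pre), pre + ref + post, pre + alt + post


def _fmt_af(ac: int, an: int) -> str:
    return repr(ac / an) if an else "0"


def _study_records(design: SimDesign, truth: dict, study_id: str,
                   rng: np.random.Generator, reference: dict) -> list[str]:
    """Assemble the study's VCF body lines (sorted, possibly denormalized)."""
    mine = [t for t in truth.values() if study_id in t.studies]
    # group multi-allelic partners sharing (chrom, start, ref)
    groups: dict = {}
    for t in mine:
        v = t.variant
        groups.setdefault((v.chrom, v.start, v.ref), []).append(t)

    lines = []
    dup_budget = design.n_duplicate_spellings
    for (chrom, start, ref), members in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
    ):
        members.sort(key=lambda t: t.variant.alt)
        multi = len(members) > 1
        passed = all(t.studies[study_id].passed for t in members)
        filt = "PASS" if passed else "q10"
        pops = [p for p, _ in next(
            s for s in design.studies if s.study_id == study_id
        ).subpops]

        def info_for(ts) -> str:
            parts = []
            acs = [t.studies[study_id].counts["ALL"][0] for t in ts]
            an = ts[0].studies[study_id].counts["ALL"][1]
            parts.append("AC=" + ",".join(str(a) for a in acs))
            parts.append(f"AN={an}")
            parts.append("AF=" + ",".join(_fmt_af(a, an) for a in acs))
            for pop in pops:
                pacs = [t.studies[study_id].counts[pop][0] for t in ts]
                pan = ts[0].studies[study_id].counts[pop][1]
                parts.append(f"AC_{pop}=" + ",".join(str(a) for a in pacs))
                parts.append(f"AN_{pop}={pan}")
                parts.append(f"AF_{pop}=" + ",".join(_fmt_af(a, pan) for a in pacs))
            return ";".join(parts)

        if multi:
            alts = ",".join(t.variant.alt for t in members)
            lines.append((chrom, start,
                          f"{chrom}\t{start}\t.\t{ref}\t{alts}\t.\t{filt}\t"
                          f"{info_for(members)}"))
            continue
        t = members[0]
        v = t.variant
        pos, rref, ralt = v.start, v.ref, v.alt
        if t.category != "long_insertion" and \
                rng.random() < design.denormalized_fraction:
            pos, rref, ralt = _denormalize(rng, reference, v)
        line = (f"{chrom}\t{pos}\t.\t{rref}\t{ralt}\t.\t{filt}\t"
                f"{info_for([t])}")
        lines.append((chrom, pos, line))
        if dup_budget > 0 and t.category == "background" \
                and rng.random() < 0.1:
            dpos, dref, dalt = _denormalize(rng, reference, v)
            if (dpos, dref, dalt) != (pos, rref, ralt):
                lines.append((chrom, dpos,
                              f"{chrom}\t{dpos}\t.\t{dref}\t{dalt}\t.\t{filt}\t"
                              f"{info_for([t])}"))
                dup_budget -= 1
    lines.sort(key=lambda x: (x[0], x[1]))
    return [l for _, _, l in lines]


def _write_vcf(design: SimDesign, truth: dict, study_id: str, path: str,
               rng: np.random.Generator, reference: dict) -> str:
    study = next(s for s in design.studies if s.study_id == study_id)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=variantstore-synthetic study={study_id}\n")
        for name, length in design.contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FILTER=<ID=q10,Description="Low quality">\n')
        for line in _VCF_INFO_HEADER:
            fh.write(line + "\n")
        for pop, _ in study.subpops:
            fh.write(f'##INFO=<ID=AC_{pop},Number=A,Type=Integer,'
                     f'Description="Allele count in {pop}">\n')
            fh.write(f'##INFO=<ID=AN_{pop},Number=1,Type=Integer,'
                     f'Description="Allele number in {pop}">\n')
            fh.write(f'##INFO=<ID=AF_{pop},Number=A,Type=Float,'
                     f'Description="Allele frequency in {pop}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for line in _study_records(design, truth, study_id, rng, reference):
            fh.write(line + "\n")
    return path


def _write_clinical(design: SimDesign, truth: dict, path: str,
                    rng: np.random.Generator, reference: dict) -> str:
    rows = []
    for t in sorted(truth.values(), key=lambda t: t.key):
        v = t.variant
        for source, significance in t.assertions:
            pos, ref, alt = v.start, v.ref, v.alt
            if rng.random() < design.denormalized_fraction:
                pos, ref, alt = _denormalize(rng, reference, v)
            rows.append((v.chrom, pos, ref, alt, source, significance))
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tsource\tlabel\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path


# -- top level ------------------------------------------------------------


def _simulate_in_memory(design: SimDesign) -> tuple[dict, dict]:
    rng = np.random.default_rng(design.seed)
    reference = _build_reference(design, rng)
    truth = _plant_variants(design, rng, reference)
    return reference, truth


def simulate(design: SimDesign, outdir: str) -> SimResult:
    """Generate reference FASTA, per-study VCFs, clinical TSV and truth."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(design.seed)
    reference = _build_reference(design, rng)
    truth = _plant_variants(design, rng, reference)

    ref_path = str(out / "reference.fa")
    with open(ref_path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    import pyfaidx

    pyfaidx.Faidx(ref_path)

    vcf_paths = {}
    for s in design.studies:
        vcf_paths[s.study_id] = _write_vcf(
            design, truth, s.study_id, str(out / f"{s.study_id}.vcf"), rng,
            reference,
        )
    clinical_path = _write_clinical(design, truth, str(out / "clinical.tsv"),
                                    rng, reference)
    return SimResult(
        design=design,
        reference=reference,
        reference_path=ref_path,
        vcf_paths=vcf_paths,
        clinical_path=clinical_path,
        truth=truth,
    )


def make_study_vcf(design: SimDesign, study_id: str, path: str):
    """Write one study's VCF (plus return its truth slice)."""
    import zlib

    reference, truth = _simulate_in_memory(design)
    rng = np.random.default_rng((design.seed, zlib.crc32(study_id.encode())))
    _write_vcf(design, truth, study_id, path, rng, reference)
    return path, {i: t for i, t in truth.items() if study_id in t.studies}


def make_clinical_table(design: SimDesign, path: str) -> str:
    """Write the design's clinical assertion TSV."""
    reference, truth = _simulate_in_memory(design)
    rng = np.random.default_rng((design.seed, 0xC11))
    return _write_clinical(design, truth, path, rng, reference)
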