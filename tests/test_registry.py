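"""Staging/production workflow, annotation import, novelty, query equivalence."""

import random

import pandas as pd
import pytest

from variantstore import keycodec as kc
from variantstore.errors import ReferenceMismatchError, UnknownStudyError
from variantstore.normalize import NormalizedVariant, RawVariant, left_align
from variantstore.registry import ClinicalAssertion, Registry
from variantstore.vcf_io import StudyObservation, read_study_vcf

from conftest import random_acgt

REF = {"1": "TGCACACACGTTTTTACGTACGTAGCTAGCTAGGGGGCATCATCATGCGC" * 8}


def snv_obs(study, pos, alt=None, passed=True, ac=2, an=100):
    base = REF["1"][pos - 1]
    alt = alt or {"A": "T", "C": "G", "G": "C", "T": "A"}[base]
    raw = RawVariant("1", pos, base, alt)
    obs = StudyObservation(
        study_id=study, counts={"ALL": (ac, an)}, af={"ALL": ac / an}, passed=passed
    )
    return raw, obs


class TestStageRegister:
    def test_restaging_same_study_finds_nothing_novel(self):
        reg = Registry(reference=REF)
        items = [snv_obs("S1", p) for p in range(5, 60, 7)]
        first = reg.stage(items)
        assert len(first.novel) == len(items) and not first.known
        reg.register(first)
        second = reg.stage(items)
        assert not second.novel and len(second.known) == len(items)

    def test_overlapping_studies_report_only_new_variants(self):
        reg = Registry(reference=REF)
        positions = list(range(5, 5 + 50 * 4, 4))
        reg.register(reg.stage([snv_obs("S1", p) for p in positions[:30]]))
        shared, fresh = positions[:10], positions[30:50]
        batch = reg.stage([snv_obs("S2", p) for p in shared + fresh])
        assert len(batch.known) == 10 and len(batch.novel) == 20
        counts = reg.register(batch)
        assert counts == {"novel_registered": 20, "sources_attached": 30}

    def test_empty_batch(self):
        reg = Registry(reference=REF)
        batch = reg.stage([])
        assert not batch.known and not batch.novel
        assert reg.register(batch) == {"novel_registered": 0, "sources_attached": 0}

    def test_one_summary_row_two_source_rows(self):
        reg = Registry(reference=REF)
        reg.ingest([snv_obs("S1", 5)])
        reg.ingest([snv_obs("S2", 5)])
        records = reg.all_records()
        assert len(records) == 1
        assert set(records[0].sources) == {"S1", "S2"}

    def test_reregistration_is_noop_for_summary(self):
        reg = Registry(reference=REF)
        reg.ingest([snv_obs("S1", 5)])
        counts = reg.ingest([snv_obs("S1", 5)])
        assert counts == {"novel_registered": 0, "sources_attached": 0}
        assert len(reg.all_records()) == 1

    def test_truncated_key_collision_disambiguated_by_allele(self):
        # two >2958 nt insertions at one locus share a truncated key
        rng = random.Random(9)
        shared = "C" + random_acgt(rng, 2958)
        alt_a, alt_b = shared + "AA", shared + "TT"
        reg = Registry(reference=REF)
        obs = StudyObservation(study_id="S1", passed=True)
        v = lambda alt: NormalizedVariant(
            build_code=37, chrom="1", chrom_code=1, start=5, end=5,
            ref="C", alt=alt, vtype="INS", effective_size=len(alt) - 1,
        )
        reg.register(reg.stage([(v(alt_a), obs)]))
        reg.register(reg.stage([(v(alt_b), obs)]))
        records = reg.all_records()
        assert len(records) == 2
        assert records[0].variant_key == records[1].variant_key
        assert {r.variant.alt for r in records} == {alt_a, alt_b}

    def test_pass_flag_or_semantics_across_duplicates(self):
        reg = Registry(reference=REF)
        reg.ingest([snv_obs("S1", 5, passed=False), snv_obs("S1", 5, passed=True)])
        assert reg.all_records()[0].sources["S1"] is True


class TestAnnotations:
    def test_unseen_variant_creates_annotation_only_record(self):
        reg = Registry(reference=REF)
        table = pd.DataFrame(
            [{"chrom": "1", "pos": 5, "ref": "C", "alt": "T",
              "source": "CLINDB", "label": "pathogenic"}]
        )
        assert reg.import_annotations(table, "clinical") == 1
        rec = reg.all_records()[0]
        assert rec.sources == {} and rec.annotations["clinical"]

    def test_reimport_is_idempotent(self):
        reg = Registry(reference=REF)
        table = pd.DataFrame(
            [{"chrom": "1", "pos": 5, "ref": "C", "alt": "T",
              "source": "CLINDB", "label": "VUS"}]
        )
        assert reg.import_annotations(table, "clinical") == 1
        assert reg.import_annotations(table, "clinical") == 0
        assert len(reg.all_records()) == 1

    def test_mismatched_ref_rejected(self):
        reg = Registry(reference=REF)
        table = pd.DataFrame(
            [{"chrom": "1", "pos": 5, "ref": "A", "alt": "T",
              "source": "X", "label": "missense"}]
        )
        with pytest.raises(ReferenceMismatchError):
            reg.import_annotations(table, "impact")

    def test_rows_keyed_by_variant_key(self):
        reg = Registry(reference=REF)
        norm = left_align(RawVariant("1", 5, "C", "T"), REF)
        key = kc.encode_key(norm).text
        table = pd.DataFrame(
            [{"variant_key": key, "source": "X", "label": "missense"}]
        )
        assert reg.import_annotations(table, "impact") == 1
        assert reg.query_by_key(key)[0].annotations["impact"]

    def test_closed_significance_vocabulary(self):
        with pytest.raises(ValueError):
            ClinicalAssertion("CLINDB", "bad_label")
        reg = Registry(reference=REF)
        table = pd.DataFrame(
            [{"chrom": "1", "pos": 5, "ref": "C", "alt": "T",
              "source": "CLINDB", "label": "not_a_label"}]
        )
        with pytest.raises(ValueError):
            reg.import_annotations(table, "clinical")


class TestNoveltyReport:
    def test_single_study_all_unique(self):
        reg = Registry(reference=REF)
        reg.ingest([snv_obs("S1", p) for p in range(5, 45, 4)])
        report = reg.novelty_report()
        assert report.loc["S1", "variants"] == 10
        assert report.loc["S1", "unique_to_study"] == 10

    def test_filter_failures_excluded_from_passed(self):
        reg = Registry(reference=REF)
        reg.ingest([snv_obs("S1", 5, passed=False), snv_obs("S1", 9, passed=True)])
        report = reg.novelty_report()
        assert report.loc["S1", "variants"] == 2
        assert report.loc["S1", "passed"] == 1

    def test_matches_generator_truth(self, sim, loaded_registry):
        report = loaded_registry.novelty_report()
        truth = sim.novelty_truth()
        assert report.sort_index().equals(
            truth.sort_index().astype(report.dtypes.to_dict())
        )


class TestOrderInvariance:
    def test_final_store_independent_of_ingestion_order(self, sim):
        import pyfaidx

        snapshots = []
        for order in (list(sim.vcf_paths), list(sim.vcf_paths)[::-1]):
            reg = Registry(":memory:", reference=pyfaidx.Fasta(sim.reference_path))
            total_novel = 0
            for study_id in order:
                counts = reg.ingest(read_study_vcf(sim.vcf_paths[study_id], study_id))
                total_novel += counts["novel_registered"]
            observed_truth = sum(1 for t in sim.truth.values() if t.studies)
            assert total_novel == observed_truth
            snapshots.append(
                {
                    (r.variant_key, r.variant.alt): (
                        dict(r.sources),
                        sorted(r.frequencies),
                    )
                    for r in reg.all_records()
                }
            )
        assert snapshots[0] == snapshots[1]


class TestQueryEquivalence:
    def test_key_location_and_prefix_scans_agree(self, loaded_registry):
        reg = loaded_registry
        for chrom_code, lo, hi in [(1, 1, 30_000), (2, 20_000, 60_000), (1, 1, 1)]:
            by_loc = {
                (r.variant_key, r.variant.alt)
                for r in reg.query_by_location(chrom_code, lo, hi)
            }
            by_prefix = {
                (r.variant_key, r.variant.alt)
                for r in reg.query_range_prefix(chrom_code, lo, hi)
            }
            assert by_loc == by_prefix
            for rec in reg.query_by_location(chrom_code, lo, hi):
                assert {
                    (r.variant_key, r.variant.alt)
                    for r in reg.query_by_key(rec.variant_key)
                } >= {(rec.variant_key, rec.variant.alt)}

    def test_dbsnp_lookup(self):
        reg = Registry(reference=REF)
        reg.ingest([snv_obs("S1", 5)])
        key = reg.all_records()[0].variant_key
        table = pd.DataFrame(
            [{"variant_key": key, "source": "X", "label": "missense",
              "dbsnp_id": "rs42"}]
        )
        reg.import_annotations(table, "impact")
        assert reg.query_by_dbsnp("rs42")[0].variant_key == key

    def test_unknown_study_raises(self, loaded_registry):
        with pytest.raises(UnknownStudyError):
            loaded_registry.assert_studies_known(["NOT_A_STUDY"])
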