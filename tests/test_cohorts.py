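"""Cohort analyses: exact test, FDR, pathogenic-common, disease-exclusive."""

import numpy as np
import pandas as pd
import pytest

from variantstore.cohorts import (
    CohortSpec,
    allele_fisher_p,
    compare_cohorts,
    exclusive_to_cohort,
    flag_pathogenic_common,
)
from variantstore.errors import CountsUnavailableError
from variantstore.registry import Registry
from variantstore.vcf_io import StudyObservation

from conftest import fisher_two_sided_oracle
from test_registry import REF, snv_obs


def _spec(study, role="healthy"):
    return CohortSpec(name=study, members=((study, None),), role=role)


class TestExactTest:
    def test_matches_enumeration_oracle_small_margins(self):
        """Exhaustive scan: all 2x2 allele tables with margins up to 12."""
        for an_a in range(1, 13):
            for an_b in range(1, 13):
                for ac_a in range(an_a + 1):
                    for ac_b in range(an_b + 1):
                        p = allele_fisher_p(ac_a, an_a, ac_b, an_b)
                        oracle = fisher_two_sided_oracle(ac_a, an_a, ac_b, an_b)
                        assert abs(p - oracle) <= 1e-12, (ac_a, an_a, ac_b, an_b)

    def test_example_table_10_of_100_vs_0_of_100(self):
        p = allele_fisher_p(10, 100, 0, 100)
        assert p == pytest.approx(fisher_two_sided_oracle(10, 100, 0, 100), abs=1e-12)

    def test_identical_counts_give_p_one(self):
        assert allele_fisher_p(7, 50, 7, 50) == pytest.approx(1.0)


class TestCompareCohorts:
    def _two_study_registry(self, counts):
        """counts: list of (pos, (ac_a, an_a) | None, (ac_b, an_b) | None)."""
        reg = Registry(reference=REF)
        for pos, a, b in counts:
            for study, c in (("A", a), ("B", b)):
                if c is None:
                    continue
                raw, _ = snv_obs(study, pos)
                obs = StudyObservation(
                    study_id=study, counts={"ALL": c},
                    af={"ALL": c[0] / c[1]}, passed=True,
                )
                reg.ingest([(raw, obs)])
        return reg

    def test_identical_counts_never_reported(self):
        reg = self._two_study_registry(
            [(5, (5, 100), (5, 100)), (9, (40, 100), (2, 100))]
        )
        hits = compare_cohorts(reg, _spec("A"), _spec("B"), alpha=0.05)
        assert len(hits) == 1
        assert hits.iloc[0]["af_a"] == pytest.approx(0.40)
        assert hits.iloc[0]["q"] < 0.05

    def test_sorted_by_q_and_counts_flagged(self):
        reg = self._two_study_registry(
            [
                (5, (50, 100), (1, 100)),
                (9, (30, 100), (2, 100)),
                (13, (10, 100), (9, 100)),
            ]
        )
        hits = compare_cohorts(reg, _spec("A"), _spec("B"), alpha=0.5)
        assert list(hits["q"]) == sorted(hits["q"])
        assert hits["counts_available"].all()

    def test_af_without_an_cannot_be_tested(self):
        reg = Registry(reference=REF)
        for study, pos in (("A", 5), ("B", 5)):
            raw, _ = snv_obs(study, pos)
            obs = StudyObservation(study_id=study, af={"ALL": 0.1 if study == "A"
                                                       else 0.4}, passed=True)
            reg.ingest([(raw, obs)])
        with pytest.raises(CountsUnavailableError):
            compare_cohorts(reg, _spec("A"), _spec("B"))

    def test_fdr_controlled_on_planted_differences(self):
        """Planted nulls vs true differences: observed FDR stays near alpha.

        Cohort allele counts are drawn binomially: 960 null variants share
        one frequency in both cohorts, 40 true signals differ 8-fold.
        Aggregated over seeds, the false-discovery proportion among hits
        must not exceed alpha by more than binomial noise.
        """
        rng = np.random.default_rng(12)
        alpha = 0.05
        an = 800
        false_hits = total_hits = 0
        for _ in range(30):
            n_null, n_true = 960, 40
            af_null = 0.02
            ps = []
            is_true = []
            for i in range(n_null + n_true):
                true = i >= n_null
                af_a = af_null if not true else 0.16
                ac_a = rng.binomial(an, af_a)
                ac_b = rng.binomial(an, af_null)
                ps.append(allele_fisher_p(ac_a, an, ac_b, an))
                is_true.append(true)
            from statsmodels.stats.multitest import multipletests

            reject = multipletests(ps, alpha=alpha, method="fdr_bh")[0]
            false_hits += int(sum(r and not t for r, t in zip(reject, is_true)))
            total_hits += int(reject.sum())
        assert total_hits > 0
        fdr = false_hits / total_hits
        # three binomial standard errors above alpha
        se = (alpha * (1 - alpha) / total_hits) ** 0.5
        assert fdr <= alpha + 3 * se


class TestFlagPathogenicCommon:
    def _registry(self, planted):
        """planted: (pos, significance, af)."""
        reg = Registry(reference=REF)
        rows = []
        for pos, significance, af in planted:
            raw, _ = snv_obs("H", pos)
            an = 10_000
            ac = int(round(af * an))
            obs = StudyObservation(
                study_id="H", counts={"ALL": (ac, an)}, af={"ALL": ac / an},
                passed=True,
            )
            reg.ingest([(raw, obs)])
            rows.append({"chrom": raw.chrom, "pos": raw.pos, "ref": raw.ref,
                         "alt": raw.alt, "source": "CLINDB",
                         "label": significance})
        reg.import_annotations(pd.DataFrame(rows), "clinical")
        return reg

    def test_pathogenic_above_threshold_flagged(self):
        reg = self._registry([(5, "pathogenic", 0.02)])
        out = flag_pathogenic_common(reg, ["H"], 0.01)
        assert len(out) == 1 and out.iloc[0]["significance"] == "pathogenic"
        assert out.iloc[0]["max_af"] == pytest.approx(0.02)

    def test_two_threshold_behaviour(self):
        reg = self._registry([(5, "pathogenic", 0.009)])
        assert flag_pathogenic_common(reg, ["H"], 0.01).empty
        strict = flag_pathogenic_common(reg, ["H"], 0.001)
        assert len(strict) == 1

    def test_benign_listed_under_benign_group(self):
        reg = self._registry([(5, "benign", 0.3), (9, "pathogenic", 0.05)])
        out = flag_pathogenic_common(reg, ["H"], 0.01)
        groups = out.groupby("significance")["variant_key"].count()
        assert groups["benign"] == 1 and groups["pathogenic"] == 1

    def test_stricter_threshold_gives_superset(self, sim, loaded_registry):
        healthy = sim.healthy_study_ids
        loose = flag_pathogenic_common(loaded_registry, healthy, 0.01)
        strict = flag_pathogenic_common(loaded_registry, healthy, 0.001)
        assert set(loose["variant_key"]) <= set(strict["variant_key"])

    def test_planted_pathogenic_common_recovered(self, sim, loaded_registry):
        healthy = sim.healthy_study_ids
        out = flag_pathogenic_common(loaded_registry, healthy, 0.01)
        flagged = set(out["variant_key"])
        # oracle: every asserted variant whose planted max AF reaches 1%
        expected = {
            t.key
            for t in sim.truth.values()
            if t.assertions and t.max_af(healthy) >= 0.01
        }
        assert flagged == expected
        assert sim.keys_in_category("pathogenic_common") <= flagged


class TestExclusiveToCohort:
    def _registry(self):
        reg = Registry(reference=REF)
        # disease-private at 5; shared with background at 9
        for study, pos, passed in (
            ("DZ", 5, True), ("DZ", 9, True), ("DZ", 13, False), ("BG", 9, True)
        ):
            reg.ingest([snv_obs(study, pos, passed=passed)])
        return reg

    def test_private_retained_shared_excluded(self):
        reg = self._registry()
        keys = exclusive_to_cohort(
            reg, _spec("DZ", "disease"), [_spec("BG")]
        )
        records = {r.variant.start for k in keys for r in reg.query_by_key(k)}
        assert records == {5, 13}

    def test_pass_filter_applies_on_request(self):
        reg = self._registry()
        keys = exclusive_to_cohort(
            reg, _spec("DZ", "disease"), [_spec("BG")], require_pass=True
        )
        records = {r.variant.start for k in keys for r in reg.query_by_key(k)}
        assert records == {5}

    def test_antitone_in_background_set(self, sim, loaded_registry):
        disease = CohortSpec(
            "dz", tuple((s, None) for s in sim.disease_study_ids), "disease"
        )
        healthy = [_spec(s) for s in sim.healthy_study_ids]
        prev = None
        for k in range(len(healthy) + 1):
            cur = set(exclusive_to_cohort(loaded_registry, disease, healthy[:k]))
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_planted_private_set_recovered_exactly(self, sim, loaded_registry):
        disease = CohortSpec(
            "dz", tuple((s, None) for s in sim.disease_study_ids), "disease"
        )
        backgrounds = [_spec(s) for s in sim.healthy_study_ids]
        got = set(exclusive_to_cohort(loaded_registry, disease, backgrounds))
        expected = {
            t.key
            for t in sim.truth.values()
            if t.studies and set(t.studies) <= set(sim.disease_study_ids)
        }
        assert got == expected
        assert sim.keys_in_category("disease_private") <= got
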