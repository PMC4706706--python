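"""Shared fixtures and independent oracles for the test-suite."""

from __future__ import annotations

import random
from fractions import Fraction
from math import comb

import pandas as pd
import pytest

from variantstore.registry import Registry
from variantstore.synthetic import SimDesign, simulate
from variantstore.vcf_io import read_study_vcf


# -- independent oracles ---------------------------------------------------


def apply_edit(contig: str, pos: int, ref: str, alt: str) -> str:
    """Apply one REF→ALT replacement at a 1-based position."""
    assert contig[pos - 1 : pos - 1 + len(ref)] == ref
    return contig[: pos - 1] + alt + contig[pos - 1 + len(ref) :]


def equivalent_spellings(
    contig: str, pos: int, ref: str, alt: str, window: int = 30, max_len: int = 40
) -> list[tuple[int, str, str]]:
    """Enumerate every raw spelling producing the same edited sequence.

    Brute force: for each candidate position and REF length near the edit,
    derive the unique ALT that makes the replacement reproduce the edited
    sequence, keeping spellings with non-empty, unequal alleles. Used as the
    normalization-convergence oracle.
    """
    mutated = apply_edit(contig, pos, ref, alt)
    delta = len(mutated) - len(contig)
    out = []
    lo = max(1, pos - window)
    hi = min(len(contig), pos + len(ref) + window)
    for p in range(lo, hi + 1):
        if contig[: p - 1] != mutated[: p - 1]:
            continue
        for lr in range(1, max_len + 1):
            if p - 1 + lr > len(contig):
                break
            la = lr + delta
            if la < 1:
                continue
            cand_ref = contig[p - 1 : p - 1 + lr]
            cand_alt = mutated[p - 1 : p - 1 + la]
            if cand_ref == cand_alt:
                continue
            if contig[p - 1 + lr :] != mutated[p - 1 + la :]:
                continue
            out.append((p, cand_ref, cand_alt))
    return out


def fisher_two_sided_oracle(ac_a: int, an_a: int, ac_b: int, an_b: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Exact integer arithmetic over all tables with the observed margins; the
    two-sided mass sums every table whose probability does not exceed the
    observed one, with the canonical 1e-7 relative tie tolerance.
    """
    a, b = ac_a, an_a - ac_a
    c, d = ac_b, an_b - ac_b
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def numerator(x: int) -> int:  # hypergeometric pmf numerator
        return comb(r1, x) * comb(n - r1, c1 - x)

    obs = numerator(a)
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    # include ties up to a 1e-7 relative tolerance: x included iff
    # numerator(x) <= obs * (1 + 1e-7), evaluated in exact arithmetic
    total = sum(
        numerator(x)
        for x in range(lo, hi + 1)
        if numerator(x) * 10**7 <= obs * (10**7 + 1)
    )
    return float(Fraction(total, comb(n, c1)))


def random_acgt(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


# -- shared synthetic dataset ---------------------------------------------


@pytest.fixture(scope="session")
def sim(tmp_path_factory):
    """One synthetic multi-study design shared across read-only tests."""
    outdir = tmp_path_factory.mktemp("sim")
    return simulate(SimDesign(seed=7), str(outdir))


@pytest.fixture(scope="session")
def loaded_registry(sim):
    """Registry with every synthetic study ingested and assertions imported.

    Session-scoped and treated as read-only; tests that mutate the store
    build their own registry.
    """
    import pyfaidx

    reg = Registry(":memory:", reference=pyfaidx.Fasta(sim.reference_path))
    for study_id, path in sim.vcf_paths.items():
        reg.ingest(read_study_vcf(path, study_id))
    reg.import_annotations(pd.read_csv(sim.clinical_path, sep="\t"), "clinical")
    return reg


@pytest.fixture()
def repeat_contig():
    """A tiny contig with repeat tracts, as a plain-dict reference."""
    return {"1": "TGCACACACGTTTTTACGTACGTAGCTAGCTAGGGGGCATCATCATGCGC"}
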