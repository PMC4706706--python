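"""Cross-cohort analyses.

A *cohort* is a named set of (study, optional subpopulation) members with a
healthy or disease role. Three analyses are provided:

* :func:`compare_cohorts` — screen for variants with significantly
  different allele frequencies between two cohorts, using a two-sided
  Fisher's exact test on the 2×2 allele-count table
  ``[(AC_a, AN_a − AC_a), (AC_b, AN_b − AC_b)]`` with Benjamini–Hochberg
  multiplicity adjustment.
* :func:`flag_pathogenic_common` — cross-check clinical assertions against
  healthy-cohort frequencies: any asserted variant whose max-ethnicity AF
  reaches the threshold (default 1%; 0.1% is a stricter alternative for
  autosomal-dominant disorders) is flagged, grouped by significance label.
* :func:`exclusive_to_cohort` — variants carried only in a disease cohort:
  AC > 0 there and zero alternate alleles in every background cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .errors import CountsUnavailableError
from .registry import Registry
from .vcf_io import OVERALL

__all__ = [
    "CohortSpec",
    "allele_fisher_p",
    "compare_cohorts",
    "flag_pathogenic_common",
    "exclusive_to_cohort",
]


def allele_fisher_p(ac_a: int, an_a: int, ac_b: int, an_b: int) -> float:
    """Two-sided Fisher's exact p for one allele-count 2×2 table.

    The table is ``[(AC_a, AN_a − AC_a), (AC_b, AN_b − AC_b)]`` — the test
    :func:`compare_cohorts` applies per variant.
    """
    return float(
        fisher_exact(
            [[ac_a, an_a - ac_a], [ac_b, an_b - ac_b]], alternative="two-sided"
        ).pvalue
    )


@dataclass(frozen=True)
class CohortSpec:
    """A named set of (study_id, subpopulation-or-None) members."""

    name: str
    members: tuple  # of (study_id, Optional[subpop])
    role: str = "healthy"  # healthy | disease

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"cohort {self.name!r} has no members")
        if self.role not in ("healthy", "disease"):
            raise ValueError(f"cohort role must be healthy or disease: {self.role!r}")

    @property
    def studies(self) -> list[str]:
        return sorted({s for s, _ in self.members})


def _cohort_counts(registry: Registry, cohort: CohortSpec) -> pd.DataFrame:
    """Per-variant summed (AC, AN) and max AF over the cohort's members.

    A member (study, None) uses the study's overall counts; a member
    (study, pop) its subpopulation counts.
    """
    registry.assert_studies_known(cohort.studies)
    frames = []
    for study, pop in cohort.members:
        subpop = OVERALL if pop is None else pop
        frames.append(
            pd.read_sql_query(
                "SELECT variant_id, ac, an, af FROM observations "
                "WHERE study_id=? AND subpop=?",
                registry.conn,
                params=(study, subpop),
            )
        )
    df = pd.concat(frames, ignore_index=True)
    if df.empty:
        return pd.DataFrame(columns=["ac", "an", "af"]).rename_axis("variant_id")
    return df.groupby("variant_id").agg(
        ac=("ac", "sum"), an=("an", "sum"), af=("af", "max")
    )


def _keys_for(registry: Registry, variant_ids: Iterable[int]) -> pd.Series:
    ids = [int(i) for i in variant_ids]  # sqlite cannot bind numpy ints
    if not ids:
        return pd.Series(dtype=object)
    placeholders = ",".join("?" * len(ids))
    df = pd.read_sql_query(
        f"SELECT id, vkey FROM variants WHERE id IN ({placeholders})",
        registry.conn,
        params=ids,
    )
    return df.set_index("id")["vkey"]


def _impact_filtered_ids(registry: Registry, filters) -> Optional[set[int]]:
    """Variant ids matching any of the requested impact labels, or None."""
    if not filters:
        return None
    labels = list(filters)
    placeholders = ",".join("?" * len(labels))
    rows = registry.conn.execute(
        f"SELECT DISTINCT variant_id FROM annotations "
        f"WHERE category='impact' AND label IN ({placeholders})",
        labels,
    ).fetchall()
    return {r[0] for r in rows}


def compare_cohorts(
    registry: Registry,
    a: CohortSpec,
    b: CohortSpec,
    alpha: float = 0.05,
    filters: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Variants with significantly different allele frequencies between cohorts.

    Tests every variant observed in either cohort with a two-sided Fisher's
    exact test on allele counts, adjusts p-values with Benjamini–Hochberg,
    and returns rows with q < ``alpha`` sorted by q (columns:
    ``variant_key, af_a, af_b, p, q, counts_available``). Variants for which
    a cohort carries AF without AN cannot be tested; they are appended with
    ``counts_available=False`` and NaN p/q, reporting the AF delta only.
    Raises :class:`CountsUnavailableError` if *no* variant is testable.
    """
    ca = _cohort_counts(registry, a)
    cb = _cohort_counts(registry, b)
    keep = _impact_filtered_ids(registry, filters)
    ids = sorted(set(ca.index) | set(cb.index))
    if keep is not None:
        ids = [i for i in ids if i in keep]
    rows, flagged = [], []
    an_a_total = ca["an"].max() if len(ca) else None
    an_b_total = cb["an"].max() if len(cb) else None
    for vid in ids:
        ra = ca.loc[vid] if vid in ca.index else None
        rb = cb.loc[vid] if vid in cb.index else None
        ac_a = int(ra["ac"]) if ra is not None and pd.notna(ra["ac"]) else 0
        ac_b = int(rb["ac"]) if rb is not None and pd.notna(rb["ac"]) else 0
        an_a = ra["an"] if ra is not None and pd.notna(ra["an"]) else an_a_total
        an_b = rb["an"] if rb is not None and pd.notna(rb["an"]) else an_b_total
        af_a = ac_a / an_a if an_a else (ra["af"] if ra is not None else 0.0)
        af_b = ac_b / an_b if an_b else (rb["af"] if rb is not None else 0.0)
        if an_a and an_b:
            rows.append((vid, float(af_a), float(af_b), ac_a, int(an_a), ac_b,
                         int(an_b)))
        else:
            flagged.append((vid, float(af_a or 0.0), float(af_b or 0.0)))
    if not rows:
        if flagged:
            raise CountsUnavailableError(
                "no cohort member exposes allele numbers; exact test impossible"
            )
        return pd.DataFrame(
            columns=["variant_key", "af_a", "af_b", "p", "q", "counts_available"]
        )
    df = pd.DataFrame(
        rows, columns=["variant_id", "af_a", "af_b", "ac_a", "an_a", "ac_b", "an_b"]
    )
    df["p"] = [
        allele_fisher_p(r.ac_a, r.an_a, r.ac_b, r.an_b) for r in df.itertuples()
    ]
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    keys = _keys_for(registry, df["variant_id"])
    df["variant_key"] = df["variant_id"].map(keys)
    df["counts_available"] = True
    hits = (
        df[df["q"] < alpha]
        .sort_values(["q", "p", "variant_key"])
        .loc[:, ["variant_key", "af_a", "af_b", "p", "q", "counts_available"]]
        .reset_index(drop=True)
    )
    if flagged:
        fk = _keys_for(registry, [v for v, _, _ in flagged])
        extra = pd.DataFrame(
            [
                {
                    "variant_key": fk.get(vid),
                    "af_a": af_a,
                    "af_b": af_b,
                    "p": float("nan"),
                    "q": float("nan"),
                    "counts_available": False,
                }
                for vid, af_a, af_b in flagged
            ]
        )
        hits = pd.concat([hits, extra], ignore_index=True)
    return hits


def flag_pathogenic_common(
    registry: Registry,
    healthy_cohorts: Iterable[str],
    threshold: float = 0.01,
    sources: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Clinically asserted variants common in healthy populations.

    Returns every asserted variant whose max-ethnicity AF across the given
    healthy studies is at least ``threshold`` (default 1% in any
    population; use 0.001 as the stricter autosomal-dominant alternative),
    grouped by significance — a pathogenic label at high AF is suspect,
    while the benign group documents expected common variation. Columns:
    ``variant_key, source, significance, max_af``, sorted by significance
    then descending AF.
    """
    from .frequencies import _max_af_frame

    studies = list(healthy_cohorts)
    registry.assert_studies_known(studies)
    clin = pd.read_sql_query(
        "SELECT variant_id, source, label AS significance FROM annotations "
        "WHERE category='clinical'",
        registry.conn,
    )
    if sources is not None:
        clin = clin[clin["source"].isin(set(sources))]
    max_af = _max_af_frame(registry, studies).set_index("variant_id")["max_af"]
    clin["max_af"] = clin["variant_id"].map(max_af).fillna(0.0)
    out = clin[clin["max_af"] >= threshold].copy()
    keys = _keys_for(registry, out["variant_id"].unique())
    out["variant_key"] = out["variant_id"].map(keys)
    return (
        out.loc[:, ["variant_key", "source", "significance", "max_af"]]
        .sort_values(["significance", "max_af", "variant_key"],
                     ascending=[True, False, True])
        .reset_index(drop=True)
    )


def exclusive_to_cohort(
    registry: Registry,
    disease: CohortSpec,
    backgrounds: Iterable[CohortSpec],
    filters: Optional[Iterable[str]] = None,
    require_pass: bool = False,
) -> list[str]:
    """Variant keys carried exclusively in the disease cohort.

    A variant qualifies when its summed AC in the disease cohort is positive
    and every background cohort shows zero alternate alleles (absence from a
    background counts as zero). Optional ``filters`` restrict to variants
    carrying one of the given imported impact labels; ``require_pass``
    additionally demands the disease study's pass flag. Adding a background
    can only shrink the result (antitone in the background set).
    """
    dz = _cohort_counts(registry, disease)
    carriers = set(dz.index[(dz["ac"].fillna(0) > 0)])
    # AF-only observations still witness presence
    carriers |= set(dz.index[(dz["af"].fillna(0) > 0)])
    for bg in backgrounds:
        cb = _cohort_counts(registry, bg)
        present = set(cb.index[(cb["ac"].fillna(0) > 0) | (cb["af"].fillna(0) > 0)])
        carriers -= present
    keep = _impact_filtered_ids(registry, filters)
    if keep is not None:
        carriers &= keep
    if require_pass and carriers:
        placeholders = ",".join("?" * len(disease.studies))
        rows = registry.conn.execute(
            f"SELECT DISTINCT variant_id FROM sources "
            f"WHERE study_id IN ({placeholders}) AND passed=1",
            disease.studies,
        ).fetchall()
        carriers &= {r[0] for r in rows}
    keys = _keys_for(registry, carriers)
    return sorted(keys.tolist())
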