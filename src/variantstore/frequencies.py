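"""Allele-frequency aggregation and binning.

For each variant the headline quantity is its *max-ethnicity allele
frequency*: the maximum AF over every (study, subpopulation) pair within a
cohort set — studies without a subpopulation breakdown contribute their
overall AF. Variants unobserved in the cohort set have max-ethnicity AF 0.

Clinically asserted variants are binned by this maximum into non-cumulative
frequency bins; intervals exclude their upper boundary and the first bin
holds exactly the unobserved / AF == 0 variants:

    0 | 0–0.001 | 0.001–0.005 | 0.005–0.01 | 0.01–0.05 | 0.05–0.1 | 0.1–0.5 | ≥0.5

The per-(source, significance) bin table reports, for each cell, the
percentage of that source's asserted variants falling into the bin —
after excluding, per source, variants carrying contradictory
pathogenicities (at least one pathogenic/likely_pathogenic AND at least one
benign/likely_benign assertion from that same source).
"""

from __future__ import annotations

from typing import Iterable, Optional

import pandas as pd

from .registry import Registry

__all__ = ["BIN_LABELS", "bin_af", "max_ethnicity_af", "clinical_bin_table"]

#: non-cumulative AF bins; upper boundaries are excluded, last bin unbounded.
BIN_EDGES = (0.001, 0.005, 0.01, 0.05, 0.1, 0.5)
BIN_LABELS = (
    "0",
    "0–0.001",
    "0.001–0.005",
    "0.005–0.01",
    "0.01–0.05",
    "0.05–0.1",
    "0.1–0.5",
    "≥0.5",
)

_PATHOGENIC = {"pathogenic", "likely_pathogenic"}
_BENIGN = {"benign", "likely_benign"}

#: ranking used to keep non-contradictory mixtures under their most severe label.
_SEVERITY = (
    "pathogenic",
    "likely_pathogenic",
    "risk_factor",
    "association",
    "drug_response",
    "protective",
    "likely_benign",
    "benign",
    "VUS",
    "other",
    "unknown",
)


def bin_af(af: float) -> str:
    """Assign an allele frequency in [0, 1] to its bin label.

    Bins are half-open with the upper boundary excluded (0.001 falls in
    "0.001–0.005"); the "0" bin contains exactly AF == 0; the last bin
    includes its lower bound 0.5.
    """
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"allele frequency outside [0, 1]: {af}")
    if af == 0.0:
        return BIN_LABELS[0]
    for i, upper in enumerate(BIN_EDGES):
        if af < upper:
            return BIN_LABELS[i + 1]
    return BIN_LABELS[-1]


def max_ethnicity_af(
    registry: Registry, variant_key: str, cohort_set: Iterable[str]
) -> float:
    """Maximum AF over every (study, subpopulation) pair in the cohort set."""
    studies = list(cohort_set)
    registry.assert_studies_known(studies)
    placeholders = ",".join("?" * len(studies))
    row = registry.conn.execute(
        f"""SELECT MAX(o.af) FROM observations o
            JOIN variants v ON v.id = o.variant_id
            WHERE v.vkey = ? AND o.study_id IN ({placeholders})
              AND o.af IS NOT NULL""",
        (variant_key, *studies),
    ).fetchone()
    return float(row[0]) if row and row[0] is not None else 0.0


def _max_af_frame(registry: Registry, studies: list[str]) -> pd.DataFrame:
    placeholders = ",".join("?" * len(studies))
    return pd.read_sql_query(
        f"""SELECT v.id AS variant_id, MAX(o.af) AS max_af
            FROM variants v LEFT JOIN observations o
              ON o.variant_id = v.id AND o.study_id IN ({placeholders})
            GROUP BY v.id""",
        registry.conn,
        params=studies,
    )


def contradictory_variant_ids(registry: Registry, source: str) -> set[int]:
    """Variants asserted both pathogenic(-like) and benign(-like) by one source."""
    df = pd.read_sql_query(
        "SELECT variant_id, label FROM annotations "
        "WHERE category='clinical' AND source=?",
        registry.conn,
        params=(source,),
    )
    out = set()
    for vid, grp in df.groupby("variant_id"):
        labels = set(grp["label"])
        if labels & _PATHOGENIC and labels & _BENIGN:
            out.add(int(vid))
    return out


def clinical_bin_table(
    registry: Registry,
    cohort_set: Iterable[str],
    sources: Optional[Iterable[str]] = None,
    decimals: int = 2,
) -> pd.DataFrame:
    """Percentage of each source's asserted variants per (significance, AF bin).

    Rows are (source, significance) pairs, columns the AF bins plus a
    ``Total`` column; cell values are percentages of the *source's* total
    asserted variant count (so each source's Total column sums to 100 up to
    rounding). Variants with contradictory pathogenicity assertions within
    a source are excluded from that source before binning; a variant with
    several non-contradictory labels is counted once, under its most severe
    label.
    """
    studies = list(cohort_set)
    registry.assert_studies_known(studies)
    clin = pd.read_sql_query(
        "SELECT variant_id, source, label FROM annotations WHERE category='clinical'",
        registry.conn,
    )
    if sources is not None:
        clin = clin[clin["source"].isin(set(sources))]
    if clin.empty:
        import warnings

        warnings.warn("no clinical assertions for the requested sources")
        return pd.DataFrame(columns=[*BIN_LABELS, "Total"])
    max_af = _max_af_frame(registry, studies).set_index("variant_id")["max_af"]

    rows = {}
    severity_rank = {lab: i for i, lab in enumerate(_SEVERITY)}
    for source, grp in clin.groupby("source"):
        excluded = contradictory_variant_ids(registry, source)
        grp = grp[~grp["variant_id"].isin(excluded)]
        # one label per variant: the most severe
        best = grp.sort_values(
            "label", key=lambda s: s.map(severity_rank)
        ).drop_duplicates("variant_id", keep="first")
        total = len(best)
        if total == 0:
            continue
        for significance, sub in best.groupby("label"):
            afs = sub["variant_id"].map(max_af).fillna(0.0)
            binned = afs.map(bin_af).value_counts()
            cells = {
                lab: round(100.0 * binned.get(lab, 0) / total, decimals)
                for lab in BIN_LABELS
            }
            cells["Total"] = round(100.0 * len(sub) / total, decimals)
            rows[(source, significance)] = cells
    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table.reindex(columns=[*BIN_LABELS, "Total"]).fillna(0.0)
    table.index = pd.MultiIndex.from_tuples(table.index, names=["source", "significance"])
    return table.sort_index()
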