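"""Cross-check clinical assertions against healthy-population frequencies.

No truly pathogenic variant should be common in healthy populations. After
importing a clinical assertion table, the store bins every asserted variant
by its maximum ethnicity-specific allele frequency across healthy cohorts
(non-cumulative bins, upper bounds excluded) and flags assertions whose
frequency reaches 1% in any population — pathogenic labels in those rows
are suspect; benign ones are expected.
"""

import tempfile

import pandas as pd
import pyfaidx

from variantstore import (
    Registry,
    SimDesign,
    clinical_bin_table,
    flag_pathogenic_common,
    read_study_vcf,
    simulate,
)

with tempfile.TemporaryDirectory() as tmp:
    sim = simulate(SimDesign(seed=1), tmp)
    registry = Registry(":memory:", reference=pyfaidx.Fasta(sim.reference_path))
    for study_id, vcf_path in sim.vcf_paths.items():
        registry.ingest(read_study_vcf(vcf_path, study_id))
    registry.import_annotations(
        pd.read_csv(sim.clinical_path, sep="\t"), "clinical"
    )

    healthy = sim.healthy_study_ids
    print("percentage of each source's variants per (significance, AF bin):")
    print(clinical_bin_table(registry, healthy).to_string())

    flagged = flag_pathogenic_common(registry, healthy, threshold=0.01)
    print(f"\nassertions with max AF >= 1% in a healthy population: {len(flagged)}")
    suspect = flagged[flagged["significance"] == "pathogenic"]
    print(f"of those, labelled pathogenic (suspect annotations): {len(suspect)}")
    print(suspect[["variant_key", "max_af"]].head().to_string(index=False))
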