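# Methods

## Canonical variant identity

A variant's identity is the tuple (build, chromosome, start, end, alternate
allele) of its **left-normalized** representation. Normalization shifts the
edit to its 5′-most equivalent position (truncating shared trailing bases
and extending with reference bases whenever an allele would empty out),
then trims redundant shared leading context down to a single anchor base.
Conventions, chosen for VCF compatibility:

- Length-changing variants always retain one 5′ anchor base; pure
  substitutions are fully trimmed. The anchor guarantees REF and ALT are
  never empty and that an insertion and an SNV at the same start cannot
  share a key (their ALT lengths differ).
- A variant at contig position 1 with no 5′ base available keeps a 3′
  anchor instead and is flagged (`anchor_3prime`); this is rare and
  preserved under re-normalization (idempotence holds for it too).
- Multi-allelic VCF records are decomposed into one raw variant per ALT
  before normalization; the store is keyed per alternate allele.
- Input is case-insensitive; canonical output is upper-case.
- `end = start + len(REF) − 1` (1-based inclusive), so an SNV has
  `end == start` and an insertion's span is its anchor base.

Left-alignment is verified two ways: idempotence on random variants, and a
brute-force oracle that enumerates *every* raw spelling reproducing the
same edited sequence within a window and checks that all of them normalize
to one key.

## Key format

The key packs (build, chromosome code, start, end, ALT length, ALT) into a
base-64 string over the byte-ordered alphabet digits `@` upper `_` lower.
Field widths are 1 + 1 + 5 + 5 + 2 symbols plus ⌈|ALT|/3⌉ allele symbols.
Numerical fields are big-endian, so at fixed width numeric order equals
byte order, and the whole key sorts genomically. Design choices:

- **Allele packing, 3 nt/symbol.** Each symbol carries a triplet over
  {A,C,G,T} (4³ = 64), zero-padded in the final triplet; the separately
  stored ALT length makes packing lossless. Packing preserves ALT
  lexicographic order at equal length, which keeps sort congruence exact.
- **1000-character cap.** An embedded-index-friendly cap; with the
  14-symbol header it yields the lossless-allele limit
  (1000 − 14) × 3 = 2958 nt. Beyond it the packed allele is truncated, the
  key flagged non-unique, and the record must be addressed by
  location + allele (the registry retains multiple records under one
  truncated key, disambiguated by allele).
- **Length-field capacity 4095** (= 64² − 1): `encode_key` rejects longer
  alleles outright.
- **Build symbol** is the GRCh number itself as an alphabet index
  (36/37/38 → `a`/`_`/`b`-adjacent symbols); reversible and
  single-symbol up to build 63.
- **Non-ACGT alleles** (N, IUPAC codes, symbolic ALTs) cannot be packed;
  they receive a positional, non-unique key with an empty allele section
  and are flagged for location + allele lookup.
- The 5-symbol position fields hold up to 64⁵ − 1 ≈ 1.07 × 10⁹, ample for
  the largest human chromosome (≈ 2.5 × 10⁸ bp).
- Chromosome codes: 1–22, X = 23, Y = 24, MT = 25; unplaced scaffolds are
  rejected in this version.

`range_prefix` returns inclusive byte-wise bounds for a (build,
chromosome, start-window) query: the lower bound is the 7-symbol prefix at
the window start; the upper bound appends the maximal symbol to the prefix
at the window end, so any well-formed key compares inside the bounds iff
its prefix fields fall inside the window.

## Registry semantics

Staging partitions a batch into known vs. novel against the production
store, merging spellings that normalize to the same identity within the
batch (pass flags OR-ed, counts first-wins since duplicates describe the
same evidence). Registration inserts novel variants with minimal summary
information immediately — they are queryable before any annotation arrives
— and attaches one source row per (variant, study) with a pass flag that
is true iff any contributing record passed (FILTER `PASS` or `.`; `.` is
treated as pass and logged). Re-registration is a no-op for summary rows.
Annotation tables attach by key or by (chrom, pos, ref, alt) normalized on
import; unmatched rows create annotation-only records with no sources,
mirroring clinical databases that assert variants never observed in a
cohort. The store is a single SQLite file with a unique index on the
identity tuple and secondary indexes on key text and (chromosome code,
start); query-by-key, query-by-location and key-prefix range scans are
tested to return identical record sets.

## Frequencies and clinical binning

The headline per-variant quantity is the **max-ethnicity AF**: the maximum
allele frequency over every (study, subpopulation) pair in a cohort set,
with unobserved variants at 0. When allele counts are present, AF is always
recomputed as AC/AN rather than trusting the file's (often
reduced-precision) AF field. Bins are non-cumulative with upper bounds
excluded: `0 | 0–0.001 | 0.001–0.005 | 0.005–0.01 | 0.01–0.05 | 0.05–0.1 |
0.1–0.5 | ≥0.5`; bin `0` holds exactly the unobserved/zero-AF variants and
`≥0.5` includes its lower bound. The bin table reports, per
(source, significance), percentages of the source's asserted variants.
A variant is *contradictory* for a source iff it carries at least one of
{pathogenic, likely_pathogenic} and at least one of {benign, likely_benign}
from that source; contradictory variants are excluded from that source's
table. Other label mixtures are kept once, under their most severe label
(severity order: pathogenic > likely_pathogenic > risk_factor >
association > drug_response > protective > likely_benign > benign > VUS >
other > unknown). Percentages are rounded to two decimals.

## Cohort analyses

- **compare_cohorts** uses a two-sided Fisher's exact test on the allele
  2×2 table [(ACₐ, ANₐ−ACₐ), (AC_b, AN_b−AC_b)] — exact at the small counts
  typical of rare variants — with Benjamini–Hochberg adjustment across all
  tested variants; hits are rows with q < α. A variant absent from one
  cohort is tested against that cohort's total allele number with AC = 0.
  Cohort members carrying AF without AN cannot be tested; such variants are
  returned flagged (`counts_available=False`) with the AF delta only, and
  the call errors only if *nothing* is testable. The p-value is checked
  against an exhaustive hypergeometric enumeration in exact integer
  arithmetic (with the canonical 1e-7 relative tie tolerance) to 1e-12.
- **flag_pathogenic_common** returns all asserted variants with
  max-ethnicity AF ≥ threshold over healthy studies, grouped by
  significance; default threshold 1% allele frequency in any population,
  with 0.1% as the stricter alternative appropriate for autosomal-dominant
  disease. Carriers are assessed on allele counts; genotype-level carrier
  logic would require genotype counts, which the store does not ingest.
- **exclusive_to_cohort** keeps variants with positive allele count in the
  disease cohort and zero alternate alleles in every background cohort
  (absence counts as zero). The result is antitone in the background set.
  Optional impact-label filters and a pass-flag filter narrow the list.

## Synthetic data

The generator emulates the structure of multi-study cohort data at toy
scale so every pipeline stage has an exact oracle: two 100 kb contigs with
homopolymer/dinucleotide repeat tracts every 5 kb (GC 0.41), three healthy
studies (200/150/100 samples with 1–3 subpopulations) plus one 50-sample
disease study, 60–120 background variants each drawn from a spectrum of
15% common / 30% low-frequency / 55% rare, 30% pairwise sharing between
healthy studies, 10% quality-filter failures, and 25% of records emitted in
non-left-aligned spellings. Planted on top: 5 pathogenic-common and 5
benign-common variants, 4 contradictory assertion pairs, 8 disease-private
variants, 2 insertions beyond the 2958 nt lossless-key limit, 4
multi-allelic sites, a few duplicate spellings of one record, 6
assertion-only variants, and 15 assorted assertions over two clinical
sources. Subpopulation AN is 2 × samples × share and AF is AC/AN exactly,
so truth-table comparisons are exact rather than approximate. All output
is a pure function of the design seed (one numpy Generator stream);
regeneration is byte-identical.

What the generator does **not** model: linkage and haplotype structure,
genotype-level data, sequencing error, reference bias, population
admixture, or annotation noise. Passing the truth-recovery tests therefore
demonstrates correct normalization, deduplication, accounting and
statistics — not robustness to caller artifacts in real data.

## Test and measurement scales

The randomized suites run at sizes chosen to finish comfortably on one
CPU: 10⁴ random variants for the encode→decode round trip and for sort
congruence; 10³ planted edits for normalization convergence with the full
spelling-enumeration oracle; Fisher agreement exhaustively over all tables
with margins ≤ 14 plus 1500 seeded random tables with margins ≤ 50; FDR
control simulated over 30 replicates of 1000 variants (40 planted
signals). The capacity script (`scripts/acceptance.py`) measures the
4095/2958 limits by bisection with ~20 and ~210 probes respectively and
cross-checks sharpness at limit + 1.

## Known limitations

- GRCh37-centric: one build per store instance; lift-over is out of scope.
- Only contigs 1–22/X/Y/MT; unplaced scaffolds are rejected.
- No BCF or tabix creation; reading indexed VCFs is supported via pysam.
- Annotation-only records carry no frequencies, so they always bin at 0.
- The embedded SQLite store targets desk-scale data (10⁶-row range), not
  the hundreds of millions of variants a production cluster would hold.
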