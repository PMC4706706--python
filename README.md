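# variantstore

An embeddable **reference variant store** for small genetic variants
(SNVs, MNVs, indels ≤ a few kb). It solves a bookkeeping problem that every
multi-study genomics platform hits: the same variant arrives from different
studies in different spellings, on different infrastructure, with
per-subpopulation allele frequencies that need to be compared across
cohorts. `variantstore` gives each variant one canonical identity and one
portable string key, then builds the standard cohort analyses on top.

It is aimed at developers of variant databases and at analysts who need
desk-scale, fully reproducible versions of the classic cohort screens:
clinical-assertion frequency cross-checks, pathogenic-but-common flagging,
and disease-exclusive variant discovery.

## The variant key

Every left-normalized variant maps to a reversible, byte-sortable base-64
string over the 64-symbol alphabet `0-9 @ A-Z _ a-z` (strictly increasing
in byte order):

| field            | symbols | content                                   |
|------------------|---------|-------------------------------------------|
| build            | 1       | GRCh build number (36/37/38)              |
| chromosome       | 1       | 1–22, X = 23, Y = 24, MT = 25             |
| start            | 5       | 1-based start, big-endian                 |
| end              | 5       | start + len(REF) − 1                      |
| ALT length       | 2       | 0–4095                                    |
| packed ALT       | rest    | 3 nucleotides per symbol (A,C,G,T = 0–3)  |

Keys are capped at 1000 characters, so alternate alleles up to
**(1000 − 14) × 3 = 2958** nucleotides are encoded losslessly (`unique=True`
and `decode_key(encode_key(v).text) == v`); longer insertions get a
truncated, potentially ambiguous key and are retrieved by location + allele
instead. Because the alphabet is byte-ordered and fields are big-endian,
sorting key strings sorts variants by (build, chromosome, start, end,
allele), and a key *prefix* delimits a chromosome/position range scan.

Around the key codec the package provides:

- `normalize` — VCF-style left-alignment with a 5′ anchor base, so every
  equivalent spelling of an indel (shifted within a repeat, padded with
  shared context) collapses to one canonical variant;
- `registry` — a single-file SQLite staging/production store with
  per-study sources, pass flags, subpopulation allele counts and imported
  annotation tables (impact, clinical significance, …);
- `frequencies` — max-ethnicity allele frequency and the non-cumulative
  AF bin table `0 | 0–0.001 | … | ≥0.5` for clinical assertions, with
  contradictory pathogenicity assertions excluded per source;
- `cohorts` — Fisher-exact allele-count comparison between cohorts with
  Benjamini–Hochberg correction, pathogenic-but-common flagging at a 1%
  (or stricter 0.1%) threshold, and disease-exclusive variant discovery;
- `synthetic` — a deterministic generator of reference FASTA, multi-study
  VCFs and clinical tables with a full truth table, so everything above is
  testable without downloads.

## Worked example

Different spellings of one deletion in a `CACACA` repeat converge to one
key (`examples/02_normalization.py`):

```
raw spelling        -> normalized          key
  6:ACA>A      -> 2:GCA>G (DEL, size 2)  _1000020000401V
  2:GCA>G      -> 2:GCA>G (DEL, size 2)  _1000020000401V
  4:ACAC>AC    -> 2:GCA>G (DEL, size 2)  _1000020000401V
  3:CACA>CA    -> 2:GCA>G (DEL, size 2)  _1000020000401V
```

All four raw records describe the same edit; the store registers a single
variant under key `_1000020000401V` (`_` = build 37, `1` = chromosome 1,
start 2, end 4, ALT length 1, packed `G`).

Ingesting the synthetic four-study design and reporting novelty
(`examples/03_build_store.py`):

```
   STUDY_A: 162 novel variants, 162 source rows attached
   STUDY_B:  97 novel variants, 139 source rows attached
   STUDY_C:  60 novel variants, 123 source rows attached
 DISEASE_D:  69 novel variants,  69 source rows attached

           variants  unique_to_study  passed
DISEASE_D        69               69      66
STUDY_A         162               93     147
STUDY_B         139               71     121
STUDY_C         123               60     109
```

`variants` counts a study's registered variants, `unique_to_study` those
seen in no other study, and `passed` those passing the study's quality
filters — all equal to the generator's planted truth. The remaining
examples cover clinical AF binning (`04`) and the cohort screens (`05`);
`examples/05_cohort_analyses.py` ends with

```
disease-exclusive variants found: 69 (generator planted 69; sets equal: True)
```

A thin CLI mirrors the library: `variantstore simulate | ingest |
annotate-vcf | import-annotations | query | report | compare | flag-common |
exclusive` and `variantstore key encode/decode`.

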