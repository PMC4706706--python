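"""Variant keys: encode, decode, and sort variants as plain strings.

Each small variant maps to one reversible base-64 string whose byte order
equals genomic order, so a plain string sort (or a string-indexed database)
keeps variants in chromosome/position order and supports prefix range scans.
"""

from variantstore import NormalizedVariant, decode_key, encode_key, range_prefix

variants = [
    NormalizedVariant(37, "1", 1, 100, 100, "C", "T", "SNV", 0),
    NormalizedVariant(37, "1", 1, 99, 101, "CAT", "C", "DEL", 2),
    NormalizedVariant(37, "2", 2, 5, 5, "G", "GAA", "INS", 2),
    NormalizedVariant(37, "X", 23, 100, 100, "A", "G", "SNV", 0),
]

keys = [encode_key(v) for v in variants]
print("variant -> key (unique?)")
for v, k in zip(variants, keys):
    print(f"  {v.chrom}:{v.start} {v.ref}>{v.alt}   {k.text}  unique={k.unique}")

print("\nbyte-sorted keys are in genomic order (chrom, position, allele):")
for text in sorted(k.text for k in keys):
    d = decode_key(text)
    print(f"  {text}  -> {d.chrom}:{d.start}-{d.end} alt={d.alt}")

lo, hi = range_prefix(build=37, chrom_code=1, start_lo=1, start_hi=100)
selected = [k.text for k in keys if lo <= k.text <= hi]
print(f"\nprefix range scan chr1:1-100 selects {len(selected)} of {len(keys)} keys")
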