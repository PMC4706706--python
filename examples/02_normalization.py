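"""Left-alignment: every spelling of one indel converges to one key.

In the CACACA repeat below, deleting any CA unit produces the same edited
sequence; callers may report the deletion at different positions or with
extra shared context. Normalization maps them all to the leftmost anchored
form, so the store deduplicates them under a single variant key.
"""

from variantstore import RawVariant, encode_key, left_align

reference = {"1": "TGCACACACGTTTTT"}

spellings = [
    RawVariant("1", 6, "ACA", "A"),    # as a caller might emit it
    RawVariant("1", 2, "GCA", "G"),    # already leftmost
    RawVariant("1", 4, "ACAC", "AC"),  # redundant shared context
    RawVariant("1", 3, "CACA", "CA"),  # shifted within the repeat
]

print("raw spelling        -> normalized          key")
for raw in spellings:
    n = left_align(raw, reference)
    key = encode_key(n).text
    print(
        f"  {raw.pos}:{raw.ref}>{raw.alt:<6} -> "
        f"{n.start}:{n.ref}>{n.alt} ({n.vtype}, size {n.effective_size})  {key}"
    )
print("\nall four spellings share one key: the store registers one variant.")
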