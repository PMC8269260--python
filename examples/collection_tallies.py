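"""Collection-level tallies on the packaged 43-isolate table.

Counts isolates per phylum and family, counts potentially novel taxa by
the 98.7% best-hit 16S rule, and shows the qPCR dCT normalization.
"""

from polytax.summaries import (
    count_novel, load_collection, qpcr_relative_expression, tally_collection,
)

table = load_collection()
print(f"collection size: {len(table)} species")

phylum = tally_collection(table, "phylum")
for taxon, count in sorted(phylum.counts.items(), key=lambda t: -t[1]):
    print(f"  {taxon:15s} n={count:2d} ({phylum.percentages[taxon]}%)")

family = tally_collection(table, "family")
print(f"families represented: {len(family.counts)}")
print(f"largest family: Lactobacillaceae n={family.counts['Lactobacillaceae']}"
      f" ({family.percentages['Lactobacillaceae']}%)")

novel = count_novel(table)
print(f"potentially novel taxa (best 16S hit <= 98.7%): {novel}")

r = qpcr_relative_expression(30.0, 10.0, gene="IgA")
print(f"qPCR example: ct_target=30, ct_reference=10 -> dCT {r.dct}, "
      f"relative expression {r.relative_expression} (40-cycle scale; "
      f"higher means more transcript)")
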