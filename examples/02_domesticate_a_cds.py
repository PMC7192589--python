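"""Domesticating a CDS that carries an internal BsaI site.

The raw sequence cannot be used in Golden Gate assembly because the internal
site would be cut. Domestication designs two PCR patches that meet at the
destroyed site, a synonymous mutation carried on the junction primers, and
grammar-tagged terminal primers; the predicted entry clone comes from
simulating the one-pot BsmBI reaction with pUPD2.
"""

from braidkit import DnaMolecule, domesticate, translate
from braidkit.backbones import default_kit
from braidkit.codon import default_usage

usage = default_usage()
# a short CDS with one internal BsaI site (GGT CTC spans Gly-Leu codons)
raw = DnaMolecule.linear(
    "ATG" + "AAAGATTTAGAACAA" * 4 + "GGTCTC" + "ATTACTGAAAGTTCA" * 4 + "TGGTAA",
    name="demo_cds",
)
plan = domesticate(raw, "CDS", pupd2=default_kit().pupd2)

print(f"raw CDS: {len(raw.seq)} nt, protein {translate(raw.seq)[:20]}...")
print(f"patches: {len(plan.patches)} (internal sites + 1)")
for i, patch in enumerate(plan.patches):
    print(f"  patch {i + 1}: span {patch.span}, junctions "
          f"{patch.junction_left}/{patch.junction_right}")
for m in plan.mutations:
    print(f"mutation: {m.ref}{m.position}{m.alt} ({m.rationale})")
print(f"head codon rewrites: {len(plan.codon_changes)} "
      f"(first 10 codons set to the most-used synonyms)")
print(f"primer pairs: {len(plan.primers)}; first forward primer 5'->3':")
print(f"  {plan.primers[0].forward.sequence}")
print(f"entry clone: {len(plan.predicted_entry_clone.seq)} bp, "
      f"translation preserved: {translate(plan.part.insert.seq) == translate(raw.seq)}")
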