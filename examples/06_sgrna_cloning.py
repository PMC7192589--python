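"""Cloning an annealed sgRNA oligo duplex with BbsI.

CRISPR spacer cloning skips PCR entirely: two complementary oligos are
annealed so the duplex already carries the 4-nt overhangs matching the
BbsI-cut CRISPR backbone. One GoldenBraid-like reaction swaps the duplex
for the backbone's drop-out cassette.
"""

from braidkit import one_pot_reaction, predict_screen
from braidkit.backbones import default_kit, sgrna_duplex
from braidkit.enzymes import BBSI

kit = default_kit()
spacer = "GATTACAGATTACAGATTAC"  # the 20-nt protospacer, minus PAM
duplex = sgrna_duplex(spacer)
print(f"annealed duplex: {duplex.seq} ({len(duplex.seq)} nt covered span)")
print(f"overhangs: {duplex.left_end.overhang} / {duplex.right_end.overhang}")

result = one_pot_reaction([duplex], kit.crispr, BBSI)
print(f"product: {len(result.desired.seq)} bp, spacer present: "
      f"{spacer in result.desired.seq}")
print(f"screen prediction: {predict_screen(result.desired, kit.crispr)}; "
      f"parental backbone: {predict_screen(kit.crispr.molecule, kit.crispr)}")
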