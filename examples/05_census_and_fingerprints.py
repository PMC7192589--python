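"""The assembly space of the starter library, and predicted fingerprints.

The census multiplies functional-class counts over the unit anatomy:
10 promoters x 28 CDS classes x 3 terminators = 840 distinct alpha1 units;
the alpha2 count drops one CDS class (non-redundancy in a binary
combination), and the omega count is their product — hundreds of thousands
of functionally distinct two-unit vectors from 68 physical parts.
"""

from braidkit import BSAI, BSMBI, count_census, enumerate_census, fingerprint
from braidkit.combinatorics import default_profile, induced_profile
from braidkit.fixtures import FixtureSpec, generate_fixtures
from braidkit.validation import gel_text

census = count_census(default_profile())
print(f"alpha1 assemblies: {census.n_alpha1}")
print(f"alpha2 assemblies (CDS classes reduced by one): {census.n_alpha2}")
print(f"omega-level combinations: {census.n_omega:,}")

# the explicit enumerator is the census's oracle on small libraries
fset = generate_fixtures(FixtureSpec(seed=1))
small = [p for p in fset.parts if p.category in ("promoter", "CDS", "terminator")][:12]
tuples = enumerate_census(small)
implied = count_census(induced_profile(small))
print(f"\nsmall-library check: {len(tuples)} enumerated == {implied.n_alpha1} counted")

# predicted restriction fingerprint of a backbone
pupd2 = fset.kit.pupd2
fp = fingerprint(pupd2.molecule, [BSMBI])
print(f"\npUPD2 x BsmBI fragments: {fp.fragment_lengths} "
      f"(sum {sum(fp.fragment_lengths)} = plasmid length)")
print(gel_text(fingerprint(fset.kit.alphas['alpha1'].molecule, [BSAI, BSMBI])))
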