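# Methods

This note documents the models behind `braidkit`: what is simulated, what is
configuration, which design choices were open, and what the synthetic
fixtures do and do not establish about real cloning.

## Sequence model

DNA is represented double-stranded with 0-based, half-open top-strand
coordinates. A linear fragment stores its *covered span* — the union of the
regions covered by either strand — so a type IIS fragment begins with its
4-nt 5' top-strand overhang (`seq[:4]`) and ends with 4 nt covered only by
the bottom strand (right overhang = `revcomp(seq[-4:])`). Two fragments
ligate exactly when the left fragment's last four bases equal the right
fragment's first four, and joining counts the shared 4-mer once. This turns
all overhang bookkeeping into string arithmetic and makes the conservation
law `len(product) = Σ (len(fragment) − 4)` exact.

Circular products are compared under **canonical rotation**: the
lexicographically least rotation over both strands (Booth's algorithm on the
sequence and its reverse complement). Ligation order produces arbitrary
rotations and orientations of the same plasmid; canonical equality is the
right equivalence.

Ambiguity codes are rejected at ingest. Parts are fully specified synthetic
sequences; expanding IUPAC codes would add cases without adding information.

## Enzymes and cutting

BsaI (`GGTCTC`, 1-nt spacer), BsmBI (`CGTCTC`, 1-nt spacer) and BbsI
(`GAAGAC`, 2-nt spacer) are modeled with their standard catalog geometry;
all three leave 4-nt 5' overhangs. For a top-strand site at `p`, the top
strand is cut at `p + 6 + spacer` and the bottom 4 nt further; bottom-strand
sites mirror this upstream. Circular molecules are scanned across the
origin. On linear molecules two refinements matter:

* a site whose cut window would run off an end is reported *uncuttable* and
  excluded from digestion (domestication scanning includes them, since it
  cares about recognition sequences, not cuttability of one molecule);
* a cut must fall inside the double-stranded region — a recognition pointing
  into an existing sticky end cannot re-cut. Without this rule a released
  drop-out cassette, which retains outward-pointing recognitions at its
  ends, would be "cut" at its own termini indefinitely.

Overlapping cut windows (two sites whose 4-nt overhang windows intersect)
are a hard error naming both sites; no clean double cut exists.

## The one-pot reaction as a fixed point

The bench protocol cycles 25× between 37 °C (cutting) and 16 °C (ligation).
Its effect is selective, not kinetic: any circular species still carrying a
recognition site of the reaction enzyme is re-opened, while species that
have lost every site accumulate. The simulator models the endpoint directly:

1. digest every input (circular donors and linear amplicons) to a fixed
   point;
2. enumerate every circular closure over the sticky fragments — each
   fragment used at most once per product (no concatemers by default), both
   orientations considered, deduplicated under canonical rotation, with
   configurable caps (12 fragments/product, 10,000 products) against
   pathological overhang sets;
3. partition closures into **stable products** (no remaining recognition
   site on either strand) and **byproducts** (parental re-closures and
   friends, which at the bench re-enter the cycle and surface as blue
   colonies when they escape).

The **desired** product is identified independently of the enumeration by
walking the grammar chain from the vector arm: each insert contributes
exactly one recognition-free sticky cargo fragment, and the walk reports the
first junction code that finds no partner — which is the diagnostic a failed
assembly needs. Overhang matching is exact and all-or-none; mismatch
ligation is not modeled, consistent with the effectively clean assemblies
the method produces. Thermodynamics, ligase efficiency, transformation and
colony counts are out of scope; the cycling parameters are recorded as
protocol metadata only.

The independent check on the enumerator is a brute-force oracle that tries
every subset, permutation and orientation vector of the fragments (feasible
to ~5 fragments); the test suite and acceptance script compare the two on
dozens of seeded reactions, including deliberately broken junctions.

## Grammar and the braided vector tiers

The grammar — the set of 4-bp fusion-site codes — is configuration, not
biology. The bundled default (`data/grammar.yaml`) is validated for ligation
fidelity: codes pairwise distinct, no palindromes (a palindromic overhang
self-ligates), and no code equal to the reverse complement of another.
Part-tier codes run `GGAG → AATG → … → CGCT` with junctions for N-tags,
C-tags, linkers and barcodes; any chain whose codes link is accepted — the
grammar, not the category label, is authoritative, which is what permits
CDS–CDS fusions.

Backbone architecture (α tier shown; pUPD2 and Ω swap the enzyme roles):

```
[core] CGTCTC·a·U5 | GGAG·a·GAGACC [lacZ] GGTCTC·a·CGCT | U3·a·GAGACG
        BsmBI out       BsaI in                BsaI in       BsmBI out
```

Entry digestion (BsaI) releases exactly two fragments — the lacZ cassette,
which carries both BsaI recognitions and is permanently lost, and the vector
arm exposing `GGAG`/`CGCT`. The assembled unit retains only the outward
BsmBI pair, which later releases the whole unit with its U5/U3 *unit codes*
— the braid. Ω backbones mirror this (BsmBI entry accepting `U0…UEND`
chains, BsaI release with `GGAG/TGGC` for Ω1 and `TGGC/CGCT` for Ω2, so two
Ω inserts re-enter an α backbone as a binary pair).

**Unit-junction scheme (open design point).** A fixed-sequence vector can
carry only one flank pair, so six named α backbones cannot serve every
k-unit chain for k = 2…5 (each k needs a closer `C_{k−1} → UEND`). The kit
assigns α1 = (U0,U1), αB = (U1,U2), αC = (U2,U3), αD = (U3,U4),
α2 = (U1,UEND) as the binary closer and αE = (U4,UEND) as the five-unit
closer, and mints deterministic closers for k = 3, 4. The 2–5-unit bound on
Ω combinations is enforced as a design rule.

The braid planner packs units greedily left-to-right into Ω groups of ≤ 5
(padding the group count to even when more than one group is needed, so the
following α round can pair Ω inserts two by two), then alternates α/Ω rounds
until one construct remains. Plan depth is not optimized beyond greedy
packing; a configurable size threshold (default 50 kb) raises a capacity
warning rather than modeling vector biology.

## Domestication

Internal BsaI/BsmBI sites are destroyed one at a time (rescanning between
fixes, since a fix can expose a new occurrence). For a CDS the substitution
must be synonymous; among all destroying synonymous single-base variants the
one maximizing the usage fraction of the new codon wins, with a
deterministic position/codon tie-break. A site admitting no such fix (e.g. a
recognition spanning only Met/Trp codons) is an explicit
"undomesticatable" error suggesting a two-codon rewrite, never a silent
miscall. Sites that exist only in the *flanked* context — spanning a grammar
code and the insert — are caught by scanning the insert together with its
constant primer context and fixed the same way, with the mutation carried on
a terminal primer.

Patch junctions are the 4 nt immediately 5' of each mutated base, slid by up
to ±6 nt to avoid collisions with grammar codes, other junctions, and
palindromes. Patches tile the sequence with 4-nt overlaps counted once, so
`patches = internal sites + 1` and ligation reconstructs the mutated
sequence exactly. Terminal primers add
`BsmBI + spacer + pUPD2-entry-code + BsaI + spacer + grammar code`;
internal primers add `BsmBI + spacer + junction code`. Annealing segments
are the shortest ≥ 18-nt stretch with nearest-neighbor Tm ≥ 60 °C (capped at
35 nt); primer secondary structure and vendor constraints are out of scope.
Elements shorter than 100 nt are flagged for annealed-oligo synthesis
instead of PCR. The predicted entry clone is not constructed by string
pasting: the reconstructed patch amplicons are run through the one-pot BsmBI
simulation with pUPD2, so every invariant of the reaction engine applies to
it.

Head optimization rewrites the first 10 codons (configurable; the useful
range is ~8–10) to the most-used synonyms from the bundled codon table,
skipping any rewrite that would create a BsaI/BsmBI site (falling back to
the next-ranked codon, ultimately keeping the original). A CDS without a
start codon is left unchanged with a warning. The bundled
*D. discoideum* table is an approximate genome-wide summary of the
organism's strong A/T-ending bias; only the per-amino-acid ranking matters
to the algorithms, and the table is user-replaceable.

## Validation predictions

Fingerprints are simultaneous complete digests (matching a ≥ 30-min
complete-digest protocol — no partials); fragment lengths are distances
between successive top-strand cuts, so they sum exactly to the molecule
length. Blue/white screening is binary with an explicit indeterminate band:
*blue* requires the intact lacZ cassette sequence in either orientation,
*white* its complete absence, and any remnant of ≥ 30 nt is
*indeterminate*. Assembly verification locates each expected part in the
canonically oriented product, reports found-in-order / missing / misordered
plus unexpected inter-part sequence, and, when given the predicted
construct, requires canonical-rotation equality — the in-silico stand-in
for Sanger confirmation.

## Combinatorial census

"Functionally distinct" means distinct tuples of functional classes;
within-class members are interchangeable. The α1 count multiplies class
counts over the slots of each permitted unit anatomy and sums over
anatomies; α2 applies the same formula with CDS classes reduced by one — a
strict assumption keeping the two units of a binary Ω combination
functionally non-redundant — and the Ω count is the α1 × α2 product. The
default profile mirrors the starter library (10 promoter, 28 CDS, 3
terminator classes) under the core P–CDS–T anatomy: 840 × 810 = 680,400 Ω
combinations. Optional tag/linker/barcode slots are supported per profile
but excluded from the default census, a conservative choice since the full
slot table of the physical library is not machine-readable; the counts are
therefore an order-of-magnitude statement, asserted in tests only as a
≥ 10⁵ bound. The explicit enumerator is the census's oracle on libraries
with one member per class and uniform category grammar slots; a
grammar-incompatible part turns the census into a strict upper bound, which
the tests demonstrate rather than hide.

## Synthetic fixtures: what they show and what they don't

The generator emulates the starter library's composition (68 elements:
10 promoters, 8 fluorescent proteins, 4 epitope tags, 2 linkers, 3
terminators, 2 luciferases, 2 Cas9s, 1 sgRNA scaffold, 13 protein CDSs, 3
drug-resistance CDSs, 20 barcodes) with AT-rich random sequence (A+T = 0.72,
the organism's genome-wide bias) and usage-weighted random codons for CDSs.
Raw-part variants carry internal sites injected at known positions for
domestication exercises: CDS injections land on codon boundaries as
`GGT|CTC` or `CGT|CTC` so a synonymous wobble fix provably exists, keep 12
codons off the optimized head and 12 nt off other sites, and are verified
against the scanner before being recorded as ground truth. Backbone
sequences are deterministic synthetic stand-ins (fixed internal seeds,
independent of the user seed) with the correct cloning architecture and a
pseudo-lacZ stuffer.

Passing tests on these fixtures establishes the *logic* of the system —
grammar fidelity, reaction selectivity, primer/patch arithmetic, census
algebra — not bench performance: real sequences bring homopolymer PCR
failures, secondary structure, star activity and transformation variance
that are deliberately outside the model.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` size their simulations to run in
seconds on one core: 200 single-site plasmids (80–400 bp bodies) for
round-trip recovery, 50 small reactions (≤ 5 fragments) against the
brute-force oracle, 8-part chains with all 16 single-code corruptions, Ω
combinations for k = 1…6, 100 random CDSs (60–140 codons) for domestication
safety, 500 molecule/enzyme pairs for fingerprint conservation, and 20
random small libraries for the census oracle. All randomness flows from
explicitly passed NumPy generators seeded from the CLI/script seed; no
global RNG state is used, and identical seeds give bit-identical fixture
files.
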