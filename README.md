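# braidkit

In-silico GoldenBraid cloning for *Dictyostelium discoideum* synthetic
biology: a simulation and design engine for hierarchical type IIS (Golden
Gate / GoldenBraid) DNA assembly.

## Who this is for

GoldenBraid builds constructs by one-pot digestion–ligation with the type
IIS enzymes **BsaI** and **BsmBI**, which cut outside their recognition
sequences and leave user-defined 4-nt sticky ends. A standardized **grammar**
of 4-bp fusion sites gives every genetic element an identity (promoter, CDS,
terminator, …) and forces parts to assemble in order; **braided** destination
vectors alternate between an α tier (BsaI entry) and an Ω tier (BsmBI entry)
so assemblies can be combined indefinitely. `braidkit` models that entire
workflow for people designing such constructs — amoeba labs adopting
modular cloning, or anyone building a Golden Gate variant — without touching
a pipette:

* **Simulation** — complete type IIS digestion, sticky-end ligation, and the
  one-pot cyclic reaction as a fixed point: the *stable* products are exactly
  the circular closures with no remaining recognition site, which is what the
  25× (37 °C / 16 °C) thermocycling enriches at the bench.
* **Domestication** — converting a raw sequence into a grammar-tagged,
  internally site-free entry clone: patch/primer design, synonymous
  single-base site removal ranked by a bundled *D. discoideum* codon-usage
  table, and optimization of the first ~10 codons for expression.
* **Planning** — α-level multipartite assembly, Ω-level combination of 2–5
  units, and multi-round braid plans executed end-to-end in the simulator.
* **Validation** — predicted restriction fingerprints, blue/white (lacZ
  drop-out) screening calls, and sequence-level verification of products.
* **Combinatorics** — the census of functionally distinct α1/α2/Ω assemblies
  a part library supports, with an exhaustive enumerator as its oracle.

The key invariant throughout: two fragments ligate iff their 4-nt 5'
overhangs are reverse complements, so a construct is a closed chain of
grammar codes `GGAG → … → CGCT`, and the census of an n-slot unit anatomy is
`Σ_patterns Π_slot (classes per slot)`.

## Worked example

Four promoter–reporter–terminator units assembled into one plasmid
(`examples/03_four_reporter_vector.py`):

```text
unit 1: promoter_01+fluorescent_protein_01+terminator_01 in pDGB_alpha1 (2550 bp, exposes GTCA/ACTG)
unit 2: promoter_02+fluorescent_protein_02+terminator_02 in pDGB_alphaB (2531 bp, exposes ACTG/CTGA)
unit 3: promoter_03+fluorescent_protein_03+terminator_03 in pDGB_alphaC (2498 bp, exposes CTGA/TCCA)
unit 4: promoter_04+fluorescent_protein_04+terminator_01 in pDGB_alpha_U3_UEND (2508 bp, exposes TCCA/GCAA)

omega product: 5328 bp carrying all four units
blue/white screen prediction: white (lacZ cassette dropped out)
unit-1 parts found in order: True
```

Each α backbone confers a position-specific pair of unit-junction codes
(e.g. `GTCA/ACTG`), so the four units can only close into the Ω vector in
the designed order; the product has lost the lacZ cassette, hence the
*white* colony prediction, while the re-ligated parental vector would screen
*blue*. The other scripts in `examples/` walk through one-pot basics,
domesticating a CDS with an internal BsaI site, planning an eight-unit braid
(two Ω reactions, then one binary α combination), the library census
(840 α1 units → 680,400 Ω combinations from 68 parts), and BbsI sgRNA-oligo
cloning.

A thin CLI wraps the same library calls:

```sh
braidkit --seed 1 fixtures --out fx/          # synthetic library + vectors
braidkit census                               # alpha1/alpha2/omega counts
braidkit fingerprint fx/backbones/pUPD2.gb --enzyme BsmBI
```

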