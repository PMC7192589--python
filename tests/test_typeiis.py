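"""Digestion, ligation and the one-pot reaction engine, checked against
brute-force oracles and Biopython's Restriction module."""

import numpy as np
import pytest

from braidkit import (
    BSAI,
    BSMBI,
    DnaMolecule,
    LigationError,
    ReactionError,
    canonical_seq,
    digest,
    find_sites,
    ligate,
    one_pot_reaction,
    revcomp,
    sticky_fragment,
)
from braidkit.typeiis import EnumerationCapError, EnumerationCaps, brute_force_closures

from conftest import site_free_dna


def sliding_window_sites(seq: str, enzyme, circular: bool) -> list[tuple[int, str]]:
    """Independent oracle: recognition occurrences by naive sliding window."""
    hay = seq + (seq[:5] if circular else "")
    out = []
    for i in range(len(seq) if circular else len(seq) - 5):
        window = hay[i : i + 6]
        if window == enzyme.recognition:
            out.append((i, "top"))
        if window == revcomp(enzyme.recognition):
            out.append((i, "bottom"))
    return out


class TestFindSites:
    def test_no_recognition_no_sites(self):
        assert find_sites(DnaMolecule.linear("ATATATATAT"), BSAI) == []

    def test_top_strand_cut_arithmetic(self):
        # GGTCTC at [2,8); spacer 1 -> top cut 9, overhang [9,13) = ACGT
        mol = DnaMolecule.linear("AAGGTCTCAACGTTT")
        (site,) = find_sites(mol, BSAI)
        assert (site.strand, site.recog_start) == ("top", 2)
        assert (site.top_cut, site.bottom_cut) == (9, 13)
        assert mol.seq[site.top_cut : site.bottom_cut] == "ACGT"

    def test_bottom_strand_mirrors_top(self):
        fwd = "AAGGTCTCAACGTTT"
        mol = DnaMolecule.linear(revcomp(fwd))
        (site,) = find_sites(mol, BSAI)
        assert site.strand == "bottom"
        # the released overhang is the reverse complement of the top case
        assert mol.seq[site.top_cut : site.bottom_cut] == revcomp("ACGT")

    def test_matches_sliding_window_oracle(self, rng):
        for circular in (False, True):
            for _ in range(20):
                seq = "".join(rng.choice(list("ACGT"), size=300))
                mol = (
                    DnaMolecule.circular(seq) if circular else DnaMolecule.linear(seq)
                )
                for enz in (BSAI, BSMBI):
                    mine = {
                        (s.recog_start, s.strand)
                        for s in find_sites(mol, enz, include_uncuttable=True)
                    }
                    oracle = set(sliding_window_sites(seq, enz, circular))
                    assert mine == oracle

    def test_matches_biopython_restriction(self, rng):
        from Bio.Restriction import BsaI as BioBsaI
        from Bio.Seq import Seq

        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=400))
            mol = DnaMolecule.linear(seq)
            mine = sorted(s.top_cut for s in find_sites(mol, BSAI))
            # Biopython reports 1-based position of the first base after the cut
            theirs = sorted(p - 1 for p in BioBsaI.search(Seq(seq), linear=True))
            assert mine == theirs

    def test_uncuttable_near_end_excluded_by_default(self):
        mol = DnaMolecule.linear("AAGGTCTCAAC")  # cut window would run off
        assert find_sites(mol, BSAI) == []
        (site,) = find_sites(mol, BSAI, include_uncuttable=True)
        assert not site.cuttable


class TestDigest:
    def test_single_cut_roundtrip(self, rng):
        seq = site_free_dna(rng, 120)
        plasmid = DnaMolecule.circular(seq[:60] + "GGTCTC" + seq[60:])
        frags = digest(plasmid, BSAI)
        assert len(frags) == 1
        (product,) = ligate(frags)
        assert product.same_plasmid_as(plasmid)

    def test_pupd2_style_two_site_digest(self, kit):
        frags = digest(kit.pupd2.molecule, BSMBI)
        assert len(frags) == 2
        assert sum(len(f.seq) - 4 for f in frags) == len(kit.pupd2.molecule.seq)
        cassette = next(f for f in frags if kit.pupd2.lacz_seq in f.seq)
        assert BSMBI.recognition in cassette.seq and BSMBI.rc_recognition in cassette.seq

    def test_length_conservation_on_random_multisite_plasmids(self, rng):
        for _ in range(15):
            chunks = [site_free_dna(rng, int(rng.integers(40, 120)))
                      for _ in range(int(rng.integers(2, 5)))]
            seq = "".join(c + "GGTCTC" for c in chunks)
            plasmid = DnaMolecule.circular(seq)
            frags = digest(plasmid, BSAI)
            assert len(frags) == len(chunks)
            assert sum(len(f.seq) - 4 for f in frags) == len(seq)
            # junction overhangs are complementary between adjacent fragments
            for i, f in enumerate(frags):
                nxt = frags[(i + 1) % len(frags)]
                assert f.right_end.ligates_to(nxt.left_end)

    def test_linear_digest_keeps_outer_ends(self):
        mol = DnaMolecule.linear("AA" + "GGTCTC" + "A" + "ACGT" + "CCCCCC")
        left, right = digest(mol, BSAI)
        assert left.left_end is None and right.right_end is None
        assert left.right_end.ligates_to(right.left_end)
        assert left.seq[-4:] == right.seq[:4] == "ACGT"

    def test_zero_sites_returns_parent(self):
        mol = DnaMolecule.circular("ATATATAT")
        assert digest(mol, BSAI) == [mol]

    def test_overlapping_cut_windows_error(self):
        # opposed sites whose overhang windows collide: top cut [7,11),
        # bottom-strand cut [8,12)
        mol = DnaMolecule.circular("GGTCTCA" + "TTTTTT" + "GAGACC" + "AATT" * 8)
        with pytest.raises(ReactionError, match="overlapping"):
            digest(mol, BSAI)


class TestLigate:
    def test_two_fragment_closure_matches_concatenation(self):
        a = sticky_fragment("GGAG" + "TTTTCCCC" + "AATG")
        b = sticky_fragment("AATG" + "GGGGAAAA" + "GGAG")
        (product,) = ligate([a, b])
        expected = DnaMolecule.circular("GGAG" + "TTTTCCCC" + "AATG" + "GGGGAAAA")
        assert product.same_plasmid_as(expected)

    def test_incompatible_overhangs_yield_nothing(self):
        a = sticky_fragment("GGAG" + "TTTTCCCC" + "AATG")
        b = sticky_fragment("CCAT" + "GGGGAAAA" + "TTCG")
        assert ligate([a, b]) == set()

    def test_self_circularization(self):
        frag = sticky_fragment("GGAG" + "TTTTAAAACCCC" + "GGAG")
        (product,) = ligate([frag])
        assert len(product.seq) == len(frag.seq) - 4

    def test_blunt_fragment_rejected(self):
        blunt = DnaMolecule.linear("AATGCCCCGGAG")
        with pytest.raises(LigationError, match="blunt"):
            ligate([blunt])

    def test_matches_bruteforce_on_random_fragment_sets(self, rng):
        codes = ["GGAG", "AATG", "GCTT", "CGCT", "TTCG"]
        for _ in range(20):
            frags = []
            k = int(rng.integers(2, 5))
            for i in range(k):
                c1, c2 = rng.choice(codes, size=2, replace=False)
                frags.append(
                    sticky_fragment(c1 + site_free_dna(rng, 20) + c2, name=f"f{i}")
                )
            mine = {canonical_seq(m.seq) for m in ligate(frags)}
            assert mine == brute_force_closures(frags)

    def test_enumeration_cap_raises(self):
        # many mutually compatible fragments blow up the closure count
        frags = [
            sticky_fragment("GGAG" + f"{a}{b}TTAACC" + "GGAG")
            for a in "ACGT" for b in "ACGT"
        ]
        with pytest.raises(EnumerationCapError):
            ligate(frags, caps=EnumerationCaps(max_products=10))


class TestOnePot:
    def test_domestication_base_case(self, fset):
        """A grammar-tagged amplicon plus pUPD2 yields the entry clone; the
        parental pUPD2 (still carrying BsmBI sites) is never stable."""
        from braidkit.grammar import ENTRY_JUNCTIONS

        rng = np.random.default_rng(5)
        insert = site_free_dna(rng, 150)
        amplicon = DnaMolecule.linear(
            "CGTCTCA" + ENTRY_JUNCTIONS["E5"] + "GGTCTCA" + "GGAG" + insert
            + "AATG" + "A" + "GAGACC" + ENTRY_JUNCTIONS["E3"] + "A" + "GAGACG",
            name="amplicon",
        )
        result = one_pot_reaction([amplicon], fset.kit.pupd2, BSMBI)
        assert result.desired is not None
        assert insert in result.desired.seq
        assert fset.kit.pupd2.molecule not in result.stable_products
        assert fset.kit.pupd2.molecule in result.byproducts
        assert find_sites(result.desired, BSMBI) == []

    def test_eight_part_chain_single_desired_product(self, kit, rng):
        from conftest import CHAIN9, make_chain_parts

        parts = make_chain_parts(CHAIN9, rng)
        assert len(parts) == 8
        result = one_pot_reaction(parts, kit.alphas["alpha1"], BSAI)
        assert result.desired is not None
        assert len(result.stable_products) == 1
        # every part present exactly once, in chain order
        doubled = result.desired.seq + result.desired.seq
        positions = []
        for p in parts:
            first = doubled.find(p.insert.seq)
            assert 0 <= first < len(result.desired.seq)
            assert doubled.find(p.insert.seq, first + 1) in (-1, first + len(result.desired.seq))
            positions.append(first)
        start = positions[0]
        assert positions == sorted(
            positions, key=lambda x: (x - start) % len(result.desired.seq)
        )

    def test_grammar_mismatch_names_junction(self, kit, rng):
        from braidkit import GrammarSite
        from conftest import make_chain_parts

        a, b = make_chain_parts(["GGAG", "AATG", "CGCT"], rng)
        b.five_site = GrammarSite("TTCG")  # deliberate mismatch at the junction
        with pytest.raises(ReactionError, match="AATG"):
            one_pot_reaction([a, b], kit.alphas["alpha1"], BSAI)
        result = one_pot_reaction([a, b], kit.alphas["alpha1"], BSAI, strict=False)
        assert result.desired is None

    def test_wrong_enzyme_for_backbone(self, kit):
        with pytest.raises(ReactionError, match="entry enzyme"):
            one_pot_reaction([], kit.alphas["alpha1"], BSMBI)

    def test_order_invariance(self, kit, cats, rng):
        parts = [cats["promoter"][0], cats["CDS"][0], cats["terminator"][0]]
        ref = one_pot_reaction(parts, kit.alphas["alpha1"], BSAI).desired
        for perm in ([2, 0, 1], [1, 2, 0], [2, 1, 0]):
            out = one_pot_reaction(
                [parts[i] for i in perm], kit.alphas["alpha1"], BSAI
            ).desired
            assert out.same_plasmid_as(ref)

    def test_length_conservation_of_desired(self, kit, cats):
        parts = [cats["promoter"][0], cats["CDS"][0], cats["terminator"][0]]
        result = one_pot_reaction(parts, kit.alphas["alpha1"], BSAI)
        arm = next(
            f for f in digest(kit.alphas["alpha1"].molecule, BSAI)
            if kit.alphas["alpha1"].lacz_seq not in f.seq
        )
        expected = (len(arm.seq) - 4) + sum(len(p.cassette().seq) - 4 for p in parts)
        assert len(result.desired.seq) == expected

    def test_stable_products_are_recognition_free(self, kit, cats):
        parts = [cats["promoter"][0], cats["CDS"][0], cats["terminator"][0]]
        result = one_pot_reaction(parts, kit.alphas["alpha1"], BSAI)
        for product in result.stable_products:
            assert find_sites(product, BSAI) == []

    def test_circular_entry_clone_donors(self, fset, kit):
        """Alpha assembly from whole entry clones (digested in the pot)
        equals assembly from released cassettes."""
        from braidkit import domesticate

        cats = fset.parts_by_category()
        parts = [cats["promoter"][2], cats["CDS"][2], cats["terminator"][2]]
        clones = [
            domesticate(p.insert, p.category, part_id=p.id,
                        pupd2=fset.kit.pupd2, optimize=False).predicted_entry_clone
            for p in parts
        ]
        via_parts = one_pot_reaction(parts, kit.alphas["alpha1"], BSAI).desired
        via_clones = one_pot_reaction(clones, kit.alphas["alpha1"], BSAI).desired
        assert via_clones.same_plasmid_as(via_parts)
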