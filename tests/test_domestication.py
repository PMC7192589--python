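"""Domestication: internal-site scanning, silent fixes, head-codon
optimization and full plans, checked with translation and scan oracles."""

import numpy as np
import pytest

from braidkit import (
    BSAI,
    BSMBI,
    CodonTable,
    DnaMolecule,
    EnzymeSpec,
    default_usage,
    domesticate,
    optimize_head,
    silent_fix,
    translate,
)
from braidkit.codon import GENETIC_CODE, SYNONYMS
from braidkit.domestication import (
    DomesticationError,
    primer_sheet,
    scan_internal,
)
from braidkit.fixtures import _random_cds

from conftest import site_free_dna


class TestScanInternal:
    def test_clean_part_is_empty(self, rng):
        assert scan_internal(DnaMolecule.linear(site_free_dna(rng, 300))) == []

    def test_single_embedded_bsmbi(self, rng):
        seq = site_free_dna(rng, 100)
        mol = DnaMolecule.linear(seq[:50] + "CGTCTC" + seq[50:])
        sites = scan_internal(mol)
        assert len(sites) == 1 and sites[0].enzyme.name == "BsmBI"
        assert sites[0].recog_start == 50

    def test_counts_match_sliding_oracle_on_2kb(self, rng):
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=2000))
            mol = DnaMolecule.linear(seq)
            oracle = sum(
                seq[i : i + 6] in ("GGTCTC", "GAGACC", "CGTCTC", "GAGACG")
                for i in range(len(seq) - 5)
            )
            assert len(scan_internal(mol)) == oracle


class TestSilentFix:
    def test_wobble_fix_destroys_site_and_preserves_protein(self):
        """GGTCTC spanning Gly-Leu codons is destroyed by a synonymous change."""
        cds = DnaMolecule.linear("ATG" + "AAA" * 5 + "GGTCTC" + "AAA" * 5 + "TAA")
        (site,) = scan_internal(cds)
        mut = silent_fix(cds, site, is_cds=True)
        fixed = cds.seq[: mut.position] + mut.alt + cds.seq[mut.position + 1 :]
        assert translate(fixed) == translate(cds.seq)
        assert scan_internal(DnaMolecule.linear(fixed)) == []

    def test_exhaustive_search_oracle(self, rng):
        """The chosen fix is the usage-highest among all synonymous single-base
        substitutions that destroy the site (independent exhaustive oracle)."""
        usage = default_usage()
        for _ in range(10):
            cds = _random_cds(rng, 40, usage)
            pos = 3 * int(rng.integers(5, 34))
            raw = cds[:pos] + "GGTCTC" + cds[pos + 6 :]
            mol = DnaMolecule.linear(raw)
            sites = scan_internal(mol)
            if len(sites) != 1:
                continue  # injection collided with context; not this test's target
            mut = silent_fix(mol, sites[0], usage, is_cds=True)
            # oracle: enumerate every synonymous single-base variant
            best = None
            for ci in range(len(raw) // 3):
                codon = raw[3 * ci : 3 * ci + 3]
                for alt in SYNONYMS[GENETIC_CODE[codon]]:
                    diffs = [k for k in range(3) if alt[k] != codon[k]]
                    if len(diffs) != 1:
                        continue
                    p = 3 * ci + diffs[0]
                    if not (pos <= p < pos + 6):
                        continue
                    cand = raw[:p] + alt[diffs[0]] + raw[p + 1 :]
                    if scan_internal(DnaMolecule.linear(cand)):
                        continue
                    frac = usage.fraction(alt)
                    if best is None or frac > best[0]:
                        best = (frac, p)
            applied = raw[: mut.position] + mut.alt + raw[mut.position + 1 :]
            assert translate(applied) == translate(raw)
            assert scan_internal(DnaMolecule.linear(applied)) == []
            assert best is not None
            chosen_codon = applied[3 * (mut.position // 3) : 3 * (mut.position // 3) + 3]
            assert usage.fraction(chosen_codon) == pytest.approx(best[0])

    def test_noncoding_any_substitution(self, rng):
        seq = site_free_dna(rng, 80)
        raw = seq[:40] + "GGTCTC" + seq[40:]
        mol = DnaMolecule.linear(raw)
        (site,) = scan_internal(mol)
        mut = silent_fix(mol, site, is_cds=False)
        assert 40 <= mut.position < 46
        fixed = raw[: mut.position] + mut.alt + raw[mut.position + 1 :]
        assert scan_internal(DnaMolecule.linear(fixed)) == []

    def test_unfixable_site_is_an_explicit_error(self):
        """A recognition spanning Met/Trp codons only admits no synonymous
        single-base escape (synthetic enzyme recognizing ATGTGG)."""
        met_trp = EnzymeSpec(name="MetTrpI", recognition="ATGTGG", spacer_len=1)
        cds = DnaMolecule.linear("ATG" + "TGG" + "AAA" * 6)
        sites = scan_internal(cds, [met_trp])
        assert sites
        with pytest.raises(DomesticationError, match="undomesticatable"):
            silent_fix(cds, sites[0], is_cds=True, avoid=[met_trp])


class TestOptimizeHead:
    def test_already_optimal_head_is_identity(self):
        usage = default_usage()
        best = "".join(usage.best_codon(aa) for aa in "MKNLIE")
        cds = DnaMolecule.linear(best + "GGG" * 4)
        out, changes = optimize_head(cds, usage, n_codons=6)
        assert out.seq == cds.seq and changes == []

    def test_table_lookup_oracle_on_toy_cds(self):
        usage = default_usage()
        aas = "MKTLPEQRSVFD"  # 12 codons
        # deliberately pick the *worst* synonymous codon everywhere
        worst = "".join(usage.ranked_synonyms(aa)[-1] for aa in aas)
        cds = DnaMolecule.linear("ATG" + worst[3:], name="toy")
        out, changes = optimize_head(cds, usage, n_codons=10)
        assert translate(out.seq) == translate(cds.seq)
        for ci in range(10):
            codon = out.seq[3 * ci : 3 * ci + 3]
            assert codon == usage.best_codon(GENETIC_CODE[codon])
        assert len(changes) == sum(
            usage.best_codon(aa) != cds.seq[3 * i : 3 * i + 3]
            for i, aa in enumerate(translate(cds.seq)[:10])
        )

    def test_fallback_when_top_codon_creates_site(self):
        """An adversarial usage table whose top codons would spell GGTCTC
        forces the second-ranked codon."""
        # Gly GGT top, Leu CTC top: GGT+CTC = GGTCTC would appear
        table = dict.fromkeys(GENETIC_CODE, 0.01)
        table.update({"GGT": 0.9, "CTC": 0.9, "GGA": 0.5, "CTT": 0.5})
        usage = CodonTable(table)
        cds = DnaMolecule.linear("ATG" + "GGG" + "CTG" + "AAA" * 5)
        out, _changes = optimize_head(cds, usage, n_codons=8)
        assert translate(out.seq) == translate(cds.seq)
        assert scan_internal(out) == []

    def test_missing_start_codon_warns_and_keeps(self):
        cds = DnaMolecule.linear("AAA" * 8)
        with pytest.warns(UserWarning, match="ATG"):
            out, changes = optimize_head(cds)
        assert out.seq == cds.seq and changes == []


class TestDomesticate:
    def test_clean_part_one_patch_two_primers(self, rng, kit):
        raw = DnaMolecule.linear(site_free_dna(rng, 250), name="promX")
        plan = domesticate(raw, "promoter", pupd2=kit.pupd2)
        assert len(plan.patches) == 1
        assert len(plan.primers) == 1  # one pair = two oligos
        assert len(primer_sheet([plan])) == 2
        assert raw.seq in plan.predicted_entry_clone.seq
        assert not plan.short_synthesis

    def test_two_sites_three_patches_six_primers(self, rng, kit):
        usage = default_usage()
        cds = _random_cds(rng, 120, usage)
        raw = cds[:90] + "GGTCTC" + cds[96:210] + "CGTCTC" + cds[216:]
        raw_mol = DnaMolecule.linear(raw, name="cdsX")
        if len(scan_internal(raw_mol)) != 2:
            pytest.skip("injection context collision (not this test's target)")
        plan = domesticate(raw_mol, "CDS", pupd2=kit.pupd2, optimize=False)
        assert len(plan.patches) == 3
        assert len(primer_sheet([plan])) == 6
        assert translate(plan.part.insert.seq) == translate(raw)

    def test_patch_tiling_reconstructs_insert(self, fset, kit):
        rp = next(
            r for r in fset.raw_parts if len(r.injected_sites) >= 1 and r.category == "CDS"
        )
        plan = domesticate(rp.raw, "CDS", part_id=rp.id, pupd2=kit.pupd2)
        final = plan.part.insert.seq
        rebuilt = ""
        for patch in plan.patches:
            s, e = patch.span
            rebuilt = rebuilt[: s] + final[s:e] if rebuilt else final[s:e]
        assert rebuilt == final
        # spans overlap by exactly the 4-nt junction
        for a, b in zip(plan.patches, plan.patches[1:]):
            assert a.span[1] - b.span[0] == 4
            assert a.junction_right == b.junction_left

    def test_idempotence(self, fset, kit):
        """Domesticating an already-domesticated CDS yields one patch, no
        mutations and no codon changes."""
        rp = next(r for r in fset.raw_parts if r.injected_sites and r.category == "CDS")
        first = domesticate(rp.raw, "CDS", part_id=rp.id, pupd2=kit.pupd2)
        again = domesticate(
            first.part.insert, "CDS", part_id=rp.id + "_redo", pupd2=kit.pupd2
        )
        assert len(again.patches) == 1
        assert again.mutations == []
        assert again.codon_changes == []

    def test_safety_on_seeded_random_library(self, fset, kit):
        """Property over the fixture library's injected raws: entry clones are
        internally site-free and CDS translation is preserved."""
        tested = 0
        for rp in fset.raw_parts:
            if not rp.injected_sites or tested >= 10:
                continue
            plan = domesticate(rp.raw, rp.category, part_id=rp.id, pupd2=kit.pupd2)
            assert len(plan.patches) == len(rp.injected_sites) + 1
            assert scan_internal(plan.part.insert) == []
            if rp.category == "CDS":
                assert translate(plan.part.insert.seq) == translate(rp.raw.seq)
            tested += 1
        assert tested >= 5

    def test_short_element_flagged_for_annealed_oligos(self, rng, kit):
        raw = DnaMolecule.linear(site_free_dna(rng, 45), name="tagX")
        plan = domesticate(raw, "N-tag", pupd2=kit.pupd2)
        assert plan.short_synthesis

    def test_primer_extensions_carry_grammar(self, rng, kit):
        raw = DnaMolecule.linear(site_free_dna(rng, 200), name="promY")
        plan = domesticate(raw, "promoter", pupd2=kit.pupd2)
        fwd = plan.primers[0].forward
        assert "CGTCTC" in fwd.extension       # BsmBI entry
        assert "GGTCTC" in fwd.extension       # BsaI assembly release
        assert fwd.extension.endswith("GGAG")  # promoter 5' grammar code
        assert fwd.anneal == raw.seq[: len(fwd.anneal)]
        assert fwd.tm_anneal >= 50.0
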