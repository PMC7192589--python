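"""The braid planner: chain validation, alpha and omega assembly, and
multi-round braid plans executed end-to-end through the simulator."""

import numpy as np
import pytest

from braidkit import (
    BSAI,
    BSMBI,
    GrammarError,
    GrammarSite,
    assemble_alpha,
    assemble_omega,
    digest,
    execute_plan,
    plan_braid,
    validate_chain,
)
from braidkit.assembly import TranscriptionalUnit

from conftest import CHAIN9, make_chain_parts


class TestValidateChain:
    def test_canonical_unit_is_ok(self, cats, kit):
        chain = [cats["promoter"][0], cats["CDS"][0], cats["terminator"][0]]
        assert validate_chain(chain, kit.alphas["alpha1"]) == []

    def test_swapped_parts_give_two_faults(self, cats, kit):
        chain = [cats["promoter"][0], cats["terminator"][0], cats["CDS"][0]]
        faults = validate_chain(chain, kit.alphas["alpha1"])
        # both internal junctions break, and the chain no longer closes on
        # the backbone flank
        assert {f.index for f in faults} == {0, 1, 2}

    def test_empty_chain_rejected(self, kit):
        with pytest.raises(ValueError, match="empty chain"):
            validate_chain([], kit.alphas["alpha1"])

    def test_every_single_corruption_is_caught(self, kit, rng):
        """Property: valid random chains pass; any one corrupted junction
        code produces at least one fault."""
        for n in (3, 5, 8):
            codes = CHAIN9[: n + 1]
            if codes[-1] != "CGCT":
                codes = codes[:-1] + ["CGCT"]
            parts = make_chain_parts(codes, rng, length=40)
            assert validate_chain(parts, kit.alphas["alpha1"]) == []
            for i in range(len(parts)):
                for attr in ("five_site", "three_site"):
                    corrupted = [p for p in parts]
                    import copy

                    victim = copy.copy(parts[i])
                    setattr(victim, attr, GrammarSite("ATCC"))
                    corrupted[i] = victim
                    assert validate_chain(corrupted, kit.alphas["alpha1"])


class TestAssembleAlpha:
    def test_product_matches_concatenation_oracle(self, cats, kit):
        chain = [cats["promoter"][0], cats["CDS"][0], cats["terminator"][0]]
        unit = assemble_alpha(chain, kit.alphas["alpha1"])
        arm = next(
            f
            for f in digest(kit.alphas["alpha1"].molecule, BSAI)
            if kit.alphas["alpha1"].lacz_seq not in f.seq
        )
        # independent oracle: vector arm + cassettes, junction 4-mers once
        expected = arm.seq[:-4]
        for p in chain:
            expected += p.five_site.code + p.insert.seq
        from braidkit import DnaMolecule

        assert unit.plasmid.same_plasmid_as(DnaMolecule.circular(expected))

    def test_eight_parts_assemble(self, kit, rng):
        parts = make_chain_parts(CHAIN9, rng)
        unit = assemble_alpha(parts, kit.alphas["alpha1"])
        assert all(p.insert.seq in unit.plasmid.seq + unit.plasmid.seq for p in parts)

    def test_empty_chain_error(self, kit):
        with pytest.raises(ValueError, match="empty chain"):
            assemble_alpha([], kit.alphas["alpha1"])

    def test_invalid_chain_raises_grammar_error(self, cats, kit):
        with pytest.raises(GrammarError, match="junction"):
            assemble_alpha(
                [cats["promoter"][0], cats["terminator"][0]], kit.alphas["alpha1"]
            )

    def test_unit_ready_for_next_level(self, cats, kit):
        """Digesting the alpha product with BsmBI releases a cassette whose
        sticky ends are the unit sites."""
        chain = [cats["promoter"][0], cats["CDS"][0], cats["terminator"][0]]
        unit = assemble_alpha(chain, kit.alphas["alpha1"])
        frags = digest(unit.plasmid, BSMBI)
        assert len(frags) == 2
        cargo = next(
            f
            for f in frags
            if BSMBI.recognition not in f.seq and BSMBI.rc_recognition not in f.seq
        )
        assert cargo.seq[:4] == unit.unit_sites[0].code
        assert cargo.seq[-4:] == unit.unit_sites[1].code


def _unit_chain(fset, k):
    """k transcriptional units assembled in position-appropriate backbones."""
    cats = fset.parts_by_category()
    alphas = fset.kit.alpha_series(k)
    units = []
    for i in range(k):
        chain = [
            cats["promoter"][i % len(cats["promoter"])],
            cats["CDS"][i % len(cats["CDS"])],
            cats["terminator"][i % len(cats["terminator"])],
        ]
        units.append(assemble_alpha(chain, alphas[i]))
    return units


class TestAssembleOmega:
    def test_two_units_minimal(self, fset):
        units = _unit_chain(fset, 2)
        product = assemble_omega(units, fset.kit.omega1)
        doubled = product.seq + product.seq
        for u in units:
            for p in u.parts:
                assert p.insert.seq in doubled

    @pytest.mark.parametrize("k", [3, 4, 5])
    def test_multipartite_combination(self, fset, k):
        units = _unit_chain(fset, k)
        product = assemble_omega(units, fset.kit.omega1)
        doubled = product.seq + product.seq
        positions = [doubled.find(u.parts[0].insert.seq) for u in units]
        assert all(p >= 0 for p in positions)
        start = positions[0]
        n = len(product.seq)
        assert positions == sorted(positions, key=lambda x: (x - start) % n)

    @pytest.mark.parametrize("k", [1, 6])
    def test_out_of_bounds_counts_refused(self, fset, k):
        units = _unit_chain(fset, min(k, 5))
        units = (units * 2)[:k] if k > 5 else units[:k]
        with pytest.raises(ValueError, match="between 2 and 5"):
            assemble_omega(units, fset.kit.omega1)

    def test_unit_junction_mismatch_diagnosed(self, fset):
        units = _unit_chain(fset, 2)
        with pytest.raises(GrammarError, match="unit chain invalid"):
            assemble_omega([units[1], units[0]], fset.kit.omega1)


class TestPlanBraid:
    def _library(self, fset):
        return {p.id: p for p in fset.parts}

    def _descriptors(self, fset, n):
        cats = fset.parts_by_category()
        return [
            [
                cats["promoter"][i % len(cats["promoter"])].id,
                cats["CDS"][i % len(cats["CDS"])].id,
                cats["terminator"][i % len(cats["terminator"])].id,
            ]
            for i in range(n)
        ]

    def test_single_unit_plan_is_one_alpha_step(self, fset):
        plan = plan_braid(self._descriptors(fset, 1), self._library(fset), fset.kit)
        assert len(plan.steps) == 1
        assert plan.steps[0].level == "alpha"

    def test_four_units_single_omega_step(self, fset):
        plan = plan_braid(self._descriptors(fset, 4), self._library(fset), fset.kit)
        omega_steps = [s for s in plan.steps if s.level == "omega"]
        assert len(omega_steps) == 1
        assert len(omega_steps[0].inputs) == 4

    def test_unknown_part_rejected(self, fset):
        with pytest.raises(KeyError, match="nonexistent"):
            plan_braid([["nonexistent"]], self._library(fset), fset.kit)

    def test_enzymes_alternate_down_every_branch(self, fset):
        for n in (1, 2, 4, 8):
            plan = plan_braid(self._descriptors(fset, n), self._library(fset), fset.kit)
            assert plan.enzymes_alternate()

    def test_eight_units_two_omegas_one_alpha_combination(self, fset):
        plan = plan_braid(self._descriptors(fset, 8), self._library(fset), fset.kit)
        assert len([s for s in plan.steps if s.level == "omega"]) == 2
        assert len([s for s in plan.steps if s.level == "alpha-combine"]) == 1

    def test_eight_unit_plan_executes_with_all_units_in_order(self, fset):
        descriptors = self._descriptors(fset, 8)
        library = self._library(fset)
        plan = plan_braid(descriptors, library, fset.kit)
        products = execute_plan(plan, library, fset.kit)
        final = products[plan.final_output]
        mol = final.plasmid if isinstance(final, TranscriptionalUnit) else final
        doubled = mol.seq + mol.seq
        positions = []
        for unit in descriptors:
            # locate each unit by its promoter+CDS junction context
            probe = (
                library[unit[0]].insert.seq[-20:]
                + library[unit[1]].five_site.code
                + library[unit[1]].insert.seq[:20]
            )
            i = doubled.find(probe)
            assert 0 <= i, f"unit {unit} not found in final construct"
            positions.append(i % len(mol.seq))
        start = positions[0]
        n = len(mol.seq)
        assert positions == sorted(positions, key=lambda x: (x - start) % n)

    def test_capacity_warning(self, fset):
        plan = plan_braid(
            self._descriptors(fset, 4), self._library(fset), fset.kit, capacity_bp=2000
        )
        assert any("capacity" in w for w in plan.warnings)
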