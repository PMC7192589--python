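"""Seeded synthetic part-library generator.

Stands in for the deposited plasmid collection: produces an AT-rich random
part library mirroring the published starter-kit composition (10 promoters,
8 fluorescent-protein CDSs, 4 epitope tags, 2 linkers, 3 terminators, 2
luciferases, 2 Cas9 CDSs, 1 sgRNA scaffold, 13 protein CDSs, 3
drug-resistance CDSs and 20 barcodes — 68 elements), the destination-vector
kit, and ground-truth metadata for domestication exercises (raw sequences
with internal BsaI/BsmBI sites injected at known, provably fixable
positions).

Identical seed + spec gives a bit-identical library. All randomness flows
from one seeded NumPy generator; the backbone sequences are fixed laboratory
plasmids and do not depend on the user seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .backbones import BackboneKit, default_kit, random_dna
from .codon import CodonTable, default_usage
from .enzymes import BSAI, BSMBI
from .grammar import DEFAULT_GRAMMAR
from .seqmodel import DnaMolecule, GrammarSet, Part
from .typeiis import find_sites

__all__ = ["FixtureSpec", "FixtureSet", "RawPart", "generate_fixtures"]

#: Published starter-library composition (element subtype -> count).
DEFAULT_COMPOSITION: dict[str, int] = {
    "promoter": 10,
    "fluorescent_protein": 8,
    "epitope_tag": 4,
    "linker": 2,
    "terminator": 3,
    "luciferase": 2,
    "cas9": 2,
    "sgRNA_scaffold": 1,
    "protein_cds": 13,
    "drug_resistance": 3,
    "barcode": 20,
}

#: Subtype -> (part category, per-member-class?, length range in nt).
_SUBTYPE_INFO: dict[str, tuple[str, bool, tuple[int, int]]] = {
    "promoter": ("promoter", True, (300, 500)),
    "fluorescent_protein": ("CDS", True, (210, 420)),
    "epitope_tag": ("N-tag", True, (27, 60)),
    "linker": ("linker", True, (18, 36)),
    "terminator": ("terminator", True, (150, 250)),
    "luciferase": ("CDS", True, (240, 420)),
    "cas9": ("CDS", True, (300, 480)),
    "sgRNA_scaffold": ("sgRNA", True, (78, 90)),
    "protein_cds": ("CDS", True, (180, 420)),
    "drug_resistance": ("CDS", True, (240, 420)),
    "barcode": ("barcode", False, (20, 20)),  # one functional class
}

_CDS_SUBTYPES = {"fluorescent_protein", "luciferase", "cas9", "protein_cds", "drug_resistance"}


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    composition: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION)
    )
    at_fraction: float = 0.72
    internal_site_rate: float = 0.25


@dataclass(frozen=True)
class InjectedSite:
    position: int
    enzyme: str
    needle: str  # the recognition text written onto the top strand


@dataclass
class RawPart:
    """An undomesticated sequence plus its injection ground truth."""

    id: str
    category: str
    raw: DnaMolecule
    injected_sites: list[InjectedSite]


@dataclass
class FixtureSet:
    spec: FixtureSpec
    parts: list[Part]
    raw_parts: list[RawPart]
    kit: BackboneKit
    grammar: GrammarSet

    def parts_by_category(self) -> dict[str, list[Part]]:
        out: dict[str, list[Part]] = {}
        for p in self.parts:
            out.setdefault(p.category, []).append(p)
        return out

    def ground_truth(self) -> dict:
        return {
            rp.id: {
                "category": rp.category,
                "length": len(rp.raw.seq),
                "injected_sites": [
                    {"position": s.position, "enzyme": s.enzyme, "needle": s.needle}
                    for s in rp.injected_sites
                ],
            }
            for rp in self.raw_parts
        }


def _site_free(seq: str) -> bool:
    for enz in (BSAI, BSMBI):
        for needle in (enz.recognition, enz.rc_recognition):
            if needle in seq:
                return False
    return True


def _random_noncoding(rng: np.random.Generator, length: int, at: float) -> str:
    p = (at / 2, (1 - at) / 2, (1 - at) / 2, at / 2)
    for _ in range(200):
        seq = random_dna(rng, length, p)
        if _site_free(seq):
            return seq
    raise RuntimeError("could not draw a site-free random sequence")  # pragma: no cover


def _random_cds(rng: np.random.Generator, n_codons: int, usage: CodonTable) -> str:
    """A random CDS: ATG start, usage-weighted codons, no stops, site-free."""
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(200):
        codons = ["ATG"]
        for _i in range(n_codons - 1):
            aa = aas[rng.integers(len(aas))]
            options = usage.weights(aa)
            codon_list = [c for c, _w in options]
            weights = np.array([w for _c, w in options], dtype=float)
            weights = weights / weights.sum() if weights.sum() else None
            codons.append(
                str(rng.choice(codon_list, p=weights))
            )
        seq = "".join(codons)
        if _site_free(seq):
            return seq
    raise RuntimeError("could not draw a site-free random CDS")  # pragma: no cover


def _inject_sites(
    rng: np.random.Generator,
    seq: str,
    is_cds: bool,
    rate: float,
) -> tuple[str, list[InjectedSite]]:
    """Write 0+ internal recognition sites into a clean sequence.

    CDS injections land on a codon boundary as the codon pair GGT|CTC (Gly,
    Leu) or CGT|CTC (Arg, Leu), so a synonymous wobble substitution in the
    Leu codon can always destroy the site later. Injections keep 12 nt off
    either end and 6 nt off each other, and are verified against the scanner.
    """
    if rng.random() >= rate:
        return seq, []
    n_sites = 1 + int(rng.random() < 0.3)  # mostly one, sometimes two
    for _attempt in range(50):
        work = seq
        placed: list[InjectedSite] = []
        ok = True
        for _k in range(n_sites):
            needle = ["GGTCTC", "CGTCTC"][rng.integers(2)]
            enzyme = "BsaI" if needle == "GGTCTC" else "BsmBI"
            if is_cds:
                n_cod = len(work) // 3
                if n_cod < 20:
                    ok = False
                    break
                ci = int(rng.integers(12, n_cod - 4))
                pos = 3 * ci
            else:
                if len(work) < 40:
                    ok = False
                    break
                pos = int(rng.integers(12, len(work) - 18))
            if any(abs(pos - s.position) < 12 for s in placed):
                ok = False
                break
            cand = work[:pos] + needle + work[pos + 6 :]
            placed.append(InjectedSite(pos, enzyme, needle))
            work = cand
        if not ok:
            continue
        mol = DnaMolecule.linear(work)
        observed = [
            s
            for enz in (BSAI, BSMBI)
            for s in find_sites(mol, enz, include_uncuttable=True)
        ]
        if len(observed) == len(placed) and {s.recog_start for s in observed} == {
            s.position for s in placed
        }:
            return work, placed
    return seq, []  # give up and leave the part clean


def generate_fixtures(spec: FixtureSpec = FixtureSpec()) -> FixtureSet:
    """Generate the synthetic library, backbones and ground truth."""
    rng = np.random.default_rng(spec.seed)
    usage = default_usage()
    grammar = DEFAULT_GRAMMAR
    parts: list[Part] = []
    raws: list[RawPart] = []

    for subtype, count in spec.composition.items():
        try:
            category, per_member_class, (lo, hi) = _SUBTYPE_INFO[subtype]
        except KeyError:
            raise ValueError(f"unknown composition subtype {subtype!r}") from None
        if category not in grammar.category_sites:
            raise ValueError(
                f"category {category!r} (subtype {subtype!r}) is absent from the "
                "grammar configuration"
            )
        five, three = grammar.sites_for_category(category)
        is_cds = subtype in _CDS_SUBTYPES
        for i in range(count):
            pid = f"{subtype}_{i + 1:02d}"
            if is_cds:
                n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
                clean = _random_cds(rng, n_codons, usage)
            else:
                length = int(rng.integers(lo, hi + 1))
                clean = _random_noncoding(rng, length, spec.at_fraction)
            func = f"{subtype}:{pid}" if per_member_class else subtype
            parts.append(
                Part(
                    id=pid,
                    insert=DnaMolecule.linear(clean, name=pid),
                    five_site=five,
                    three_site=three,
                    category=category,
                    functional_class=func,
                    is_cds=is_cds,
                    forbidden=(BSAI, BSMBI),
                )
            )
            injected, sites = _inject_sites(rng, clean, is_cds, spec.internal_site_rate)
            raws.append(
                RawPart(
                    id=pid,
                    category=category,
                    raw=DnaMolecule.linear(injected, name=pid),
                    injected_sites=sites,
                )
            )

    return FixtureSet(
        spec=spec, parts=parts, raw_parts=raws, kit=default_kit(), grammar=grammar
    )
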