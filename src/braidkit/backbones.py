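"""Deterministic builders for the GoldenBraid destination vectors.

These model the fixed laboratory plasmids of the system: the domestication
entry vector pUPD2, the alpha-level backbones (alpha1, alpha2, alphaB-E), the
omega-level backbones (omega1, omega2) and a BbsI sgRNA cloning vector. The
sequences are synthetic stand-ins with the correct cloning architecture: a
lacZ-alpha drop-out cassette for blue/white screening, braided type IIS sites
in the published orientation, and marker annotations matching the tier
(carbenicillin for pUPD2, kanamycin for alpha, chloramphenicol for omega).

Architecture of an alpha backbone (top strand, clockwise)::

    [core: ori + markers]
    CGTCTC a U5          <- BsmBI, arm side: release overhang for the omega round
    GGAG a GAGACC        <- BsaI, cassette side: entry overhang GGAG
    [lacZ stuffer]
    GGTCTC a CGCT        <- BsaI, cassette side: entry overhang CGCT
    U3 a GAGACG          <- BsmBI, arm side

Digesting with the entry enzyme (BsaI) releases exactly two fragments: the
lacZ cassette (carrying both BsaI recognitions, hence lost for good) and the
vector arm whose sticky ends are the flank codes GGAG/CGCT. The assembled
product retains only the outward BsmBI pair, which later releases the whole
transcriptional unit with the U5/U3 unit codes — the "braid". pUPD2 and the
omega backbones are the same pattern with the enzyme roles swapped.

All sequences are generated from fixed internal seeds, so they are identical
across runs and independent of any user-facing fixture seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enzymes import BBSI, BSAI, BSMBI
from .grammar import DEFAULT_GRAMMAR, ENTRY_JUNCTIONS, PART_JUNCTIONS, UNIT_JUNCTIONS
from .seqmodel import Backbone, DnaMolecule, Feature, GrammarSite, revcomp, sticky_fragment

__all__ = [
    "random_dna",
    "scrub_sites",
    "BackboneKit",
    "build_pupd2",
    "build_alpha",
    "build_omega",
    "build_crispr_backbone",
    "default_kit",
    "sgrna_duplex",
    "SGRNA_FLANKS",
]

_AT_RICH = (0.36, 0.14, 0.14, 0.36)  # A C G T — the organism's AT-rich genome


def random_dna(rng: np.random.Generator, length: int, probs=_AT_RICH) -> str:
    return "".join(rng.choice(["A", "C", "G", "T"], size=length, p=list(probs)))


def scrub_sites(seq: str, enzymes=(BSAI, BSMBI, BBSI)) -> str:
    """Remove every recognition occurrence of the given enzymes, both strands.

    Deterministic: the third base of each offending hexamer is cycled until
    the occurrence (and any newly created one) disappears.
    """
    needles = [e.recognition for e in enzymes] + [e.rc_recognition for e in enzymes]
    s = list(seq)
    changed = True
    guard = 0
    while changed:
        changed = False
        guard += 1
        if guard > 10 * len(seq) + 100:  # pragma: no cover - defensive
            raise RuntimeError("site scrubbing failed to converge")
        text = "".join(s)
        for needle in needles:
            i = text.find(needle)
            if i != -1:
                pos = i + 2
                order = "ACGT"
                s[pos] = order[(order.index(s[pos]) + 1) % 4]
                changed = True
                break
    return "".join(s)


def _lacz_stuffer(seed: int = 7, length: int = 420) -> str:
    """Deterministic synthetic lacZ-alpha stand-in (site-free)."""
    rng = np.random.default_rng(seed)
    return scrub_sites(random_dna(rng, length, (0.25, 0.25, 0.25, 0.25)))


def _core(seed: int, length: int, marker_label: str) -> tuple[str, list]:
    rng = np.random.default_rng(seed)
    seq = scrub_sites(random_dna(rng, length))
    feats = [
        ("ColE1 ori", 10, min(length, 510)),
        (marker_label, min(length, 520), min(length, 520 + 660)),
    ]
    return seq, feats


_A = "A"  # the 1-nt spacer used between recognition and overhang


def _assemble_backbone(
    bb_id: str,
    level: str,
    core_seed: int,
    core_len: int,
    marker_label: str,
    pre_cassette: str,
    cassette_left: str,
    cassette_right: str,
    post_cassette: str,
    entry_enzyme,
    flank: tuple[str, str],
    unit: tuple[str, str] | None,
    release_enzyme,
    amoeba_marker: str = "none",
) -> Backbone:
    core, core_feats = _core(core_seed, core_len, marker_label)
    stuffer = _lacz_stuffer()
    seq = pre_cassette + cassette_left + stuffer + cassette_right + post_cassette + core
    lacz_start = len(pre_cassette + cassette_left)
    lacz_end = lacz_start + len(stuffer)
    feats = [Feature("lacZ-alpha", lacz_start, lacz_end, 1)]
    core_off = len(seq) - len(core)
    for label, s, e in core_feats:
        feats.append(Feature(label, core_off + s, core_off + e, 1))
    mol = DnaMolecule.circular(seq, name=bb_id, annotations=feats)
    # the architecture must carry exactly two entry sites (cassette drop-out)
    # and, where a release enzyme exists, exactly two release sites
    from .typeiis import find_sites

    n_entry = len(find_sites(mol, entry_enzyme))
    if n_entry != 2:  # pragma: no cover - construction guard
        raise RuntimeError(f"{bb_id}: {n_entry} {entry_enzyme.name} sites (expected 2)")
    if release_enzyme is not None:
        n_rel = len(find_sites(mol, release_enzyme))
        if n_rel != 2:  # pragma: no cover - construction guard
            raise RuntimeError(
                f"{bb_id}: {n_rel} {release_enzyme.name} sites (expected 2)"
            )
    g = DEFAULT_GRAMMAR
    site = lambda code: next(
        (s for s in g.sites.values() if s.code == code), GrammarSite(code)
    )
    return Backbone(
        id=bb_id,
        level=level,
        molecule=mol,
        entry_enzyme=entry_enzyme,
        lacz_span=(lacz_start, lacz_end),
        flank_sites=(site(flank[0]), site(flank[1])),
        unit_sites=(site(unit[0]), site(unit[1])) if unit else None,
        release_enzyme=release_enzyme,
        amoeba_marker=amoeba_marker,
    )


def build_pupd2() -> Backbone:
    """The domestication entry vector: BsmBI entry, universal E5/E3 ends."""
    e5, e3 = ENTRY_JUNCTIONS["E5"], ENTRY_JUNCTIONS["E3"]
    return _assemble_backbone(
        "pUPD2",
        "pUPD2",
        core_seed=101,
        core_len=1400,
        marker_label="CarbR (bla)",
        pre_cassette="",
        cassette_left=e5 + _A + BSMBI.rc_recognition,      # E5 a GAGACG
        cassette_right=BSMBI.recognition + _A + e3,        # CGTCTC a E3
        post_cassette="",
        entry_enzyme=BSMBI,
        flank=(e5, e3),
        unit=None,
        # part release uses BsaI sites carried on the domestication primers,
        # not on the backbone itself
        release_enzyme=None,
    )


def build_alpha(
    bb_id: str,
    level: str,
    unit5: str,
    unit3: str,
    core_seed: int,
    amoeba_marker: str = "G418",
) -> Backbone:
    """An alpha-level backbone: BsaI entry (GGAG/CGCT), BsmBI release (U5/U3)."""
    unit5_c = UNIT_JUNCTIONS.get(unit5, unit5)
    unit3_c = UNIT_JUNCTIONS.get(unit3, unit3)
    ggag = PART_JUNCTIONS["unit5"]
    cgct = PART_JUNCTIONS["unit3"]
    return _assemble_backbone(
        bb_id,
        level,
        core_seed=core_seed,
        core_len=1600,
        marker_label="KanR",
        pre_cassette=BSMBI.recognition + _A + unit5_c,           # CGTCTC a U5
        cassette_left=ggag + _A + BSAI.rc_recognition,           # GGAG a GAGACC
        cassette_right=BSAI.recognition + _A + cgct,             # GGTCTC a CGCT
        post_cassette=unit3_c + _A + BSMBI.rc_recognition,       # U3 a GAGACG
        entry_enzyme=BSAI,
        flank=(ggag, cgct),
        unit=(unit5_c, unit3_c),
        release_enzyme=BSMBI,
        amoeba_marker=amoeba_marker,
    )


def build_omega(
    bb_id: str, level: str, outer5: str, outer3: str, core_seed: int,
    amoeba_marker: str = "hygromycin",
) -> Backbone:
    """An omega-level backbone: BsmBI entry (U0/UEND), BsaI release (outer codes)."""
    u0 = UNIT_JUNCTIONS["U0"]
    uend = UNIT_JUNCTIONS["UEND"]
    o5 = UNIT_JUNCTIONS.get(outer5, PART_JUNCTIONS.get(outer5, outer5))
    o3 = UNIT_JUNCTIONS.get(outer3, PART_JUNCTIONS.get(outer3, outer3))
    return _assemble_backbone(
        bb_id,
        level,
        core_seed=core_seed,
        core_len=1600,
        marker_label="CmR",
        pre_cassette=BSAI.recognition + _A + o5,                 # GGTCTC a outer5
        cassette_left=u0 + _A + BSMBI.rc_recognition,            # U0 a GAGACG
        cassette_right=BSMBI.recognition + _A + uend,            # CGTCTC a UEND
        post_cassette=o3 + _A + BSAI.rc_recognition,             # outer3 a GAGACC
        entry_enzyme=BSMBI,
        flank=(u0, uend),
        unit=(o5, o3),
        release_enzyme=BSAI,
        amoeba_marker=amoeba_marker,
    )


#: Overhangs for annealed sgRNA oligo cloning into the BbsI CRISPR backbone.
SGRNA_FLANKS = ("TGTA", "AAAC")


def build_crispr_backbone() -> Backbone:
    """pDGB_A2_CRISPR1-style vector: BbsI drop-out for annealed sgRNA oligos."""
    j1, j2 = SGRNA_FLANKS
    spacer2 = "AA"  # BbsI cuts 2 nt downstream of its recognition
    return _assemble_backbone(
        "pDGB_A2_CRISPR1",
        "alpha2",
        core_seed=131,
        core_len=1600,
        marker_label="KanR",
        pre_cassette="",
        cassette_left=j1 + spacer2 + BBSI.rc_recognition,        # J1 aa GTCTTC
        cassette_right=BBSI.recognition + spacer2 + j2,          # GAAGAC aa J2
        post_cassette="",
        entry_enzyme=BBSI,
        flank=(j1, j2),
        unit=None,
        release_enzyme=None,
        amoeba_marker="G418",
    )


def sgrna_duplex(spacer20: str, name: str = "sgRNA-oligos") -> DnaMolecule:
    """The annealed complementary oligo pair for sgRNA cloning.

    Models ordering two single-stranded oligos whose annealed duplex carries
    the BbsI-compatible 4-nt overhangs directly (no PCR, no digestion).
    """
    if len(spacer20) != 20:
        raise ValueError("sgRNA spacer must be 20 nt")
    j1, j2 = SGRNA_FLANKS
    return sticky_fragment(j1 + spacer20 + j2, name=name)


# Position codes of the unit-junction chain: a unit assembled in the alpha
# backbone at chain position i carries (codes[i], codes[i+1]) — except the
# last unit of a k-chain, which must close with UEND.
_CHAIN = ["U0", "U1", "U2", "U3", "U4"]


@dataclass
class BackboneKit:
    """The full destination-vector set, plus deterministic position closers.

    The six named alpha backbones cover the start and middle chain positions
    and the binary (alpha2) and five-unit (alphaE) closers; for 3- and 4-unit
    omega combinations the kit mints deterministic closer backbones
    (C2->UEND, C3->UEND), since a fixed-sequence vector can only carry one
    flank pair.
    """

    pupd2: Backbone
    alphas: dict[str, Backbone]
    omega1: Backbone
    omega2: Backbone
    crispr: Backbone
    _minted: dict[str, Backbone] = field(default_factory=dict)

    def by_id(self) -> dict[str, Backbone]:
        out = {self.pupd2.id: self.pupd2, self.omega1.id: self.omega1,
               self.omega2.id: self.omega2, self.crispr.id: self.crispr}
        out.update({b.id: b for b in self.alphas.values()})
        out.update(self._minted)
        return out

    def omega_for_parity(self, parity: int) -> Backbone:
        return self.omega1 if parity % 2 == 0 else self.omega2

    def alpha_for(self, unit5: str, unit3: str) -> Backbone:
        """Alpha backbone with the given unit-junction pair, minting if needed."""
        for bb in list(self.alphas.values()) + list(self._minted.values()):
            if bb.unit_sites and (bb.unit_sites[0].code, bb.unit_sites[1].code) == (
                UNIT_JUNCTIONS.get(unit5, unit5),
                UNIT_JUNCTIONS.get(unit3, unit3),
            ):
                return bb
        bb_id = f"pDGB_alpha_{unit5}_{unit3}"
        seed = 200 + sum(ord(c) for c in unit5 + unit3) % 97
        bb = build_alpha(bb_id, "alpha1", unit5, unit3, core_seed=seed)
        self._minted[bb_id] = bb
        return bb

    def alpha_series(self, k: int) -> list[Backbone]:
        """Alpha backbones for a k-unit omega chain, in position order."""
        if k < 1:
            raise ValueError("need at least one unit")
        if k == 1:
            return [self.alpha_for("U0", "U1")]
        if k > len(_CHAIN):
            raise ValueError(f"at most {len(_CHAIN)} units per omega reaction")
        series = []
        for i in range(k):
            five = _CHAIN[i]
            three = "UEND" if i == k - 1 else _CHAIN[i + 1]
            series.append(self.alpha_for(five, three))
        return series


def default_kit() -> BackboneKit:
    """The standard vector set with the published naming."""
    alphas = {
        "alpha1": build_alpha("pDGB_alpha1", "alpha1", "U0", "U1", core_seed=102),
        "alpha2": build_alpha("pDGB_alpha2", "alpha2", "U1", "UEND", core_seed=103),
        "alphaB": build_alpha("pDGB_alphaB", "alphaB", "U1", "U2", core_seed=104),
        "alphaC": build_alpha("pDGB_alphaC", "alphaC", "U2", "U3", core_seed=105),
        "alphaD": build_alpha("pDGB_alphaD", "alphaD", "U3", "U4", core_seed=106),
        "alphaE": build_alpha("pDGB_alphaE", "alphaE", "U4", "UEND", core_seed=107),
    }
    return BackboneKit(
        pupd2=build_pupd2(),
        alphas=alphas,
        omega1=build_omega("pDGB_omega1", "omega1", "unit5", "OMID", core_seed=108),
        omega2=build_omega("pDGB_omega2", "omega2", "OMID", "unit3", core_seed=109),
        crispr=build_crispr_backbone(),
    )
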