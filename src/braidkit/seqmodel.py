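"""Core domain types for type IIS (Golden Gate / GoldenBraid) cloning.

Everything downstream — digestion, ligation, assembly planning, domestication
and validation — is built on the types in this module:

* :class:`DnaMolecule` — a fully specified double-stranded DNA sequence with
  linear or circular topology and, for linear molecules, optional 4-nt 5'
  sticky ends.
* :class:`StickyEnd` — a 4-nt 5' single-stranded protrusion.
* :class:`EnzymeSpec` — geometry of a type IIS enzyme (BsaI, BsmBI, BbsI).
* :class:`GrammarSite` / :class:`GrammarSet` — the standardized 4-bp fusion
  sites ("grammar") that encode part identity and enforce assembly order.
* :class:`Part` — a domesticated genetic element flanked by grammar sites.
* :class:`Backbone` — a destination vector (pUPD2 / alpha / omega levels) with
  a lacZ drop-out cassette for blue/white screening.

Sequence representation
-----------------------
Coordinates are 0-based, half-open, on the top strand. A linear molecule with
sticky ends stores the *covered span*: the union of the regions covered by
either strand. A fragment produced by type IIS digestion therefore begins with
its 4-nt 5'-top overhang (``seq[:4]``, top strand only) and ends with the 4 nt
covered by the bottom strand only (so the right-end overhang, read 5'->3' on
the bottom strand, is ``revcomp(seq[-4:])``). Two fragments ligate exactly
when the left fragment's last four bases equal the right fragment's first
four; joining concatenates the covered spans counting the shared 4-mer once.
This makes overhang bookkeeping pure string arithmetic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

__all__ = [
    "SequenceError",
    "TopologyError",
    "GrammarError",
    "Feature",
    "StickyEnd",
    "DnaMolecule",
    "EnzymeSpec",
    "GrammarSite",
    "GrammarSet",
    "Part",
    "Backbone",
    "revcomp",
    "canonical_rotation",
    "canonical_seq",
    "sticky_fragment",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")

PART_CATEGORIES = (
    "promoter",
    "CDS",
    "N-tag",
    "C-tag",
    "linker",
    "terminator",
    "barcode",
    "sgRNA",
    "other",
)


class SequenceError(ValueError):
    """A sequence contains characters outside {A, C, G, T}."""


class TopologyError(ValueError):
    """An operation received a molecule of the wrong topology."""


class GrammarError(ValueError):
    """A grammar set or grammar chain violates the ligation-fidelity rules."""


def _check_acgt(seq: str) -> str:
    seq = seq.upper()
    for i, base in enumerate(seq):
        if base not in _VALID:
            raise SequenceError(
                f"non-ACGT character {base!r} at position {i}; ambiguity codes "
                "are rejected — parts must be fully specified"
            )
    return seq


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (involution: revcomp∘revcomp = id)."""
    seq = _check_acgt(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def _least_rotation(s: str) -> int:
    """Index of the lexicographically least rotation (Booth's algorithm)."""
    n = len(s)
    s2 = s + s
    f = [-1] * len(s2)
    k = 0
    for j in range(1, len(s2)):
        sj = s2[j]
        i = f[j - k - 1]
        while i != -1 and sj != s2[k + i + 1]:
            if sj < s2[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s2[k + i + 1]:
            if sj < s2[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def canonical_seq(seq: str) -> str:
    """Canonical form of a circular sequence over both strands.

    The lexicographically smallest string among all rotations of the top
    strand and all rotations of the bottom strand. Two circular molecules are
    the same plasmid iff their canonical forms match, regardless of which
    rotation or strand the ligation happened to produce.
    """
    if not seq:
        return seq
    seq = _check_acgt(seq)
    rc = revcomp(seq)
    i = _least_rotation(seq)
    j = _least_rotation(rc)
    return min(seq[i:] + seq[:i], rc[j:] + rc[:j])


@dataclass(frozen=True)
class Feature:
    """An annotated span: 0-based half-open coordinates on the top strand."""

    label: str
    start: int
    end: int
    strand: int = 1

    def __post_init__(self) -> None:
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1 or -1, got {self.strand}")
        if not (0 <= self.start <= self.end):
            raise ValueError(f"bad feature span [{self.start}, {self.end})")


@dataclass(frozen=True)
class StickyEnd:
    """A 4-nt 5' single-stranded overhang.

    ``overhang`` is the protruding sequence read 5'->3' on its own strand.
    Two sticky ends ligate iff their overhangs are reverse complements and
    they protrude from opposite strands.
    """

    overhang: str
    protruding_strand: Literal["five_prime_top", "five_prime_bottom"]

    def __post_init__(self) -> None:
        object.__setattr__(self, "overhang", _check_acgt(self.overhang))
        if len(self.overhang) != 4:
            raise ValueError(
                f"overhang must be exactly 4 nt (got {self.overhang!r}); the "
                "modeled enzymes all generate 4-base sticky ends"
            )
        if self.protruding_strand not in ("five_prime_top", "five_prime_bottom"):
            raise ValueError(f"bad protruding_strand {self.protruding_strand!r}")

    def ligates_to(self, other: "StickyEnd") -> bool:
        return (
            self.protruding_strand != other.protruding_strand
            and self.overhang == revcomp(other.overhang)
        )

    @property
    def top_code(self) -> str:
        """The junction 4-mer in top-strand orientation (grammar code)."""
        if self.protruding_strand == "five_prime_top":
            return self.overhang
        return revcomp(self.overhang)


@dataclass(eq=False)
class DnaMolecule:
    """A double-stranded DNA molecule, linear or circular.

    For linear molecules ``seq`` is the covered span (see module docstring);
    blunt ends are represented by ``None``. Circular molecules never carry
    sticky ends. Equality is sequence identity: canonical-rotation equality
    over both strands for circular molecules, covered-span + end equality
    for linear ones; names and annotations are not compared.
    """

    seq: str
    topology: Literal["linear", "circular"] = "linear"
    left_end: Optional[StickyEnd] = None
    right_end: Optional[StickyEnd] = None
    annotations: list[Feature] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        self.seq = _check_acgt(self.seq)
        if self.topology not in ("linear", "circular"):
            raise TopologyError(f"unknown topology {self.topology!r}")
        if self.topology == "circular" and (self.left_end or self.right_end):
            raise TopologyError("circular molecules cannot have sticky ends")
        for f in self.annotations:
            if f.end > len(self.seq):
                raise ValueError(
                    f"feature {f.label!r} [{f.start},{f.end}) exceeds sequence "
                    f"length {len(self.seq)}"
                )
        if self.left_end is not None:
            if self.left_end.protruding_strand != "five_prime_top":
                raise ValueError("left end of a fragment must protrude on the top strand")
            if self.seq[:4] != self.left_end.overhang:
                raise ValueError("left overhang must equal seq[:4] (covered-span convention)")
        if self.right_end is not None:
            if self.right_end.protruding_strand != "five_prime_bottom":
                raise ValueError("right end of a fragment must protrude on the bottom strand")
            if revcomp(self.seq[-4:]) != self.right_end.overhang:
                raise ValueError("right overhang must equal revcomp(seq[-4:])")

    # -- constructors ------------------------------------------------------
    @classmethod
    def linear(cls, seq: str, name: str = "", annotations: Iterable[Feature] = ()) -> "DnaMolecule":
        """A blunt linear molecule (e.g. a raw part or a PCR amplicon)."""
        return cls(seq=seq, topology="linear", name=name, annotations=list(annotations))

    @classmethod
    def circular(cls, seq: str, name: str = "", annotations: Iterable[Feature] = ()) -> "DnaMolecule":
        return cls(seq=seq, topology="circular", name=name, annotations=list(annotations))

    # -- identity ----------------------------------------------------------
    def _key(self) -> tuple:
        if self.topology == "circular":
            return ("circular", canonical_seq(self.seq))
        return ("linear", self.seq, self.left_end, self.right_end)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DnaMolecule):
            return NotImplemented
        return self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())

    # -- basic properties --------------------------------------------------
    def __len__(self) -> int:
        return len(self.seq)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    @property
    def is_sticky(self) -> bool:
        """True when both ends carry 5' overhangs (ligatable fragment)."""
        return (
            self.topology == "linear"
            and self.left_end is not None
            and self.right_end is not None
        )

    @property
    def canonical(self) -> str:
        """Canonical rotation (circular molecules only)."""
        return canonical_rotation(self)

    def reverse_complement(self) -> "DnaMolecule":
        """The same physical molecule read from the other strand."""
        n = len(self.seq)
        feats = [
            Feature(f.label, n - f.end, n - f.start, -f.strand) for f in self.annotations
        ]
        if self.topology == "circular":
            return DnaMolecule.circular(revcomp(self.seq), name=self.name, annotations=feats)
        rc = revcomp(self.seq)
        left = (
            StickyEnd(rc[:4], "five_prime_top") if self.right_end is not None else None
        )
        right = (
            StickyEnd(revcomp(rc[-4:]), "five_prime_bottom")
            if self.left_end is not None
            else None
        )
        return DnaMolecule(
            seq=rc, topology="linear", left_end=left, right_end=right,
            name=self.name, annotations=feats,
        )

    def rotated(self, k: int) -> "DnaMolecule":
        """Rotate a circular molecule so position ``k`` becomes the origin."""
        if not self.is_circular:
            raise TopologyError("rotation is only defined for circular molecules")
        n = len(self.seq)
        k %= n
        feats = []
        for f in self.annotations:
            s, e = (f.start - k) % n, (f.end - k) % n
            if s < e:  # drop features that would wrap the new origin
                feats.append(Feature(f.label, s, e, f.strand))
        return DnaMolecule.circular(self.seq[k:] + self.seq[:k], name=self.name, annotations=feats)

    def contains(self, subseq: str, both_strands: bool = True) -> bool:
        """Does the molecule contain ``subseq`` (origin-spanning matches included)?"""
        subseq = _check_acgt(subseq)
        hay = self.seq + (self.seq[: len(subseq) - 1] if self.is_circular else "")
        if subseq in hay:
            return True
        return both_strands and revcomp(subseq) in hay

    def same_plasmid_as(self, other: "DnaMolecule") -> bool:
        if not (self.is_circular and other.is_circular):
            raise TopologyError("plasmid equality is defined for circular molecules")
        return canonical_seq(self.seq) == canonical_seq(other.seq)


def canonical_rotation(mol: DnaMolecule) -> str:
    """Canonical form of a circular molecule (both strands, all rotations)."""
    if not mol.is_circular:
        raise TopologyError("canonical_rotation requires a circular molecule")
    return canonical_seq(mol.seq)


def sticky_fragment(seq: str, name: str = "", annotations: Iterable[Feature] = ()) -> DnaMolecule:
    """Build a linear fragment with 4-nt 5' overhangs at both ends.

    ``seq`` is the covered span; the left overhang is ``seq[:4]`` (top) and
    the right overhang is ``revcomp(seq[-4:])`` (bottom).
    """
    seq = _check_acgt(seq)
    if len(seq) < 8:
        raise ValueError("a doubly-sticky fragment needs at least 8 nt of covered span")
    return DnaMolecule(
        seq=seq,
        topology="linear",
        left_end=StickyEnd(seq[:4], "five_prime_top"),
        right_end=StickyEnd(revcomp(seq[-4:]), "five_prime_bottom"),
        name=name,
        annotations=list(annotations),
    )


@dataclass(frozen=True)
class EnzymeSpec:
    """Geometry of a type IIS restriction enzyme.

    The enzyme binds ``recognition`` and cuts downstream: the top strand
    ``spacer_len`` nt after the recognition 3' end, the bottom strand a
    further ``overhang_len`` nt along, leaving a 5' overhang.
    """

    name: str
    recognition: str
    spacer_len: int
    overhang_len: int = 4
    cuts_outside: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "recognition", _check_acgt(self.recognition))
        if self.spacer_len < 0:
            raise ValueError("spacer_len must be >= 0")
        if self.overhang_len != 4:
            raise ValueError("only 4-nt overhangs are modeled (overhang_len must be 4)")
        if self.recognition == revcomp(self.recognition):
            raise ValueError(
                f"{self.name}: palindromic recognition {self.recognition!r} is not "
                "type IIS as modeled here"
            )

    @property
    def rc_recognition(self) -> str:
        return revcomp(self.recognition)


@dataclass(frozen=True)
class GrammarSite:
    """A 4-bp fusion-site code with a human-readable junction label."""

    code: str
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "code", _check_acgt(self.code))
        if len(self.code) != 4:
            raise GrammarError(f"grammar code must be 4 nt, got {self.code!r}")


class GrammarSet:
    """An ordered mapping of junction names to :class:`GrammarSite` codes.

    Enforces ligation fidelity across the set: codes are pairwise distinct,
    none is a palindrome, and none equals the reverse complement of another
    (otherwise two designed junctions could cross-ligate).
    """

    def __init__(self, sites: dict[str, GrammarSite],
                 category_sites: Optional[dict[str, tuple[str, str]]] = None) -> None:
        self.sites: dict[str, GrammarSite] = dict(sites)
        self.category_sites = dict(category_sites or {})
        self._validate()
        for cat, (five, three) in self.category_sites.items():
            for junction in (five, three):
                if junction not in self.sites:
                    raise GrammarError(
                        f"category {cat!r} refers to unknown junction {junction!r}"
                    )
            if five == three:
                raise GrammarError(f"category {cat!r}: five_site equals three_site")

    def _validate(self) -> None:
        codes = [s.code for s in self.sites.values()]
        if len(set(codes)) != len(codes):
            dup = sorted({c for c in codes if codes.count(c) > 1})
            raise GrammarError(f"duplicate grammar codes: {dup}")
        for name, site in self.sites.items():
            if site.code == revcomp(site.code):
                raise GrammarError(
                    f"junction {name!r}: palindromic code {site.code} would self-ligate"
                )
        for name, site in self.sites.items():
            for other_name, other in self.sites.items():
                if name < other_name and site.code == revcomp(other.code):
                    raise GrammarError(
                        f"junctions {name!r} and {other_name!r} are reverse "
                        f"complements ({site.code}/{other.code}): ligation fidelity lost"
                    )

    def __getitem__(self, junction: str) -> GrammarSite:
        return self.sites[junction]

    def __contains__(self, junction: str) -> bool:
        return junction in self.sites

    def codes(self) -> set[str]:
        return {s.code for s in self.sites.values()}

    def sites_for_category(self, category: str) -> tuple[GrammarSite, GrammarSite]:
        """Default (five_site, three_site) pair for a part category."""
        try:
            five, three = self.category_sites[category]
        except KeyError:
            raise GrammarError(
                f"category {category!r} has no junction assignment in this grammar"
            ) from None
        return self.sites[five], self.sites[three]


@dataclass
class Part:
    """A domesticated genetic element with its grammar flanks.

    ``insert`` is the bare part sequence (no grammar codes); its released
    assembly cassette is ``five_site.code + insert + three_site.code``.
    A domesticated part's insert never contains a BsaI or BsmBI recognition
    sequence on either strand — checked at construction against the enzymes
    passed in ``forbidden`` (defaults set by :func:`Part.__post_init__`).
    """

    id: str
    insert: DnaMolecule
    five_site: GrammarSite
    three_site: GrammarSite
    category: str = "other"
    functional_class: str = ""
    is_cds: bool = False
    forbidden: Sequence[EnzymeSpec] = ()
    validate: bool = True

    def __post_init__(self) -> None:
        if self.insert.topology != "linear" or self.insert.left_end or self.insert.right_end:
            raise ValueError(f"part {self.id!r}: insert must be a blunt linear molecule")
        if self.category not in PART_CATEGORIES:
            raise ValueError(
                f"part {self.id!r}: unknown category {self.category!r} "
                f"(expected one of {PART_CATEGORIES})"
            )
        if self.five_site.code == self.three_site.code:
            raise GrammarError(f"part {self.id!r}: five_site equals three_site")
        if not self.functional_class:
            self.functional_class = self.category
        if self.validate and self.forbidden:
            for enz in self.forbidden:
                for needle in (enz.recognition, enz.rc_recognition):
                    if needle in self.insert.seq:
                        raise GrammarError(
                            f"part {self.id!r} is not domesticated: internal "
                            f"{enz.name} site ({needle}) at position "
                            f"{self.insert.seq.find(needle)}"
                        )
        if self.is_cds and not self.insert.seq.startswith("ATG"):
            raise ValueError(f"CDS part {self.id!r} must start with ATG")

    def cassette(self) -> DnaMolecule:
        """The sticky fragment released by the assembly-level digestion."""
        return sticky_fragment(
            self.five_site.code + self.insert.seq + self.three_site.code,
            name=f"{self.id}.cassette",
            annotations=[Feature(self.id, 4, 4 + len(self.insert.seq), 1)],
        )


BACT_MARKER_BY_LEVEL = {
    "pUPD2": "carbenicillin",
    "alpha": "kanamycin",
    "omega": "chloramphenicol",
}


def _level_group(level: str) -> str:
    if level == "pUPD2":
        return "pUPD2"
    if level.startswith("alpha"):
        return "alpha"
    if level.startswith("omega"):
        return "omega"
    raise ValueError(f"unknown backbone level {level!r}")


@dataclass
class Backbone:
    """A destination vector with a lacZ drop-out cassette.

    ``flank_sites`` are the grammar codes the vector arm exposes on
    entry-enzyme digestion, in chain order: the first is where the first
    insert attaches, the second is where the last insert closes back onto the
    arm. ``unit_sites`` (alpha levels) are the codes the assembled product
    will expose at the *next* braid level; ``release_enzyme`` is the enzyme of
    that next level.
    """

    id: str
    level: str
    molecule: DnaMolecule
    entry_enzyme: EnzymeSpec
    lacz_span: tuple[int, int]
    flank_sites: tuple[GrammarSite, GrammarSite]
    unit_sites: Optional[tuple[GrammarSite, GrammarSite]] = None
    release_enzyme: Optional[EnzymeSpec] = None
    bact_marker: str = ""
    amoeba_marker: str = "none"

    def __post_init__(self) -> None:
        group = _level_group(self.level)
        if not self.molecule.is_circular:
            raise TopologyError(f"backbone {self.id!r}: molecule must be circular")
        s, e = self.lacz_span
        if not (0 <= s < e <= len(self.molecule.seq)):
            raise ValueError(f"backbone {self.id!r}: bad lacz_span {self.lacz_span}")
        if not self.bact_marker:
            self.bact_marker = BACT_MARKER_BY_LEVEL[group]
        expected = BACT_MARKER_BY_LEVEL[group]
        if self.bact_marker != expected:
            raise ValueError(
                f"backbone {self.id!r}: bacterial marker {self.bact_marker!r} does not "
                f"match level {self.level!r} (expected {expected!r})"
            )

    @property
    def lacz_seq(self) -> str:
        s, e = self.lacz_span
        return self.molecule.seq[s:e]
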