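"""Counting the combinatorial assembly space of a part library.

"Functionally distinct" assemblies are distinct tuples of functional
classes: swapping one mCherry allele for another does not create a new
functional design, but swapping mCherry for a luciferase does. The census
multiplies class counts over the slots of each permitted unit anatomy:

* alpha1 count  = sum over slot patterns of the product of class counts;
* alpha2 count  = the same with the number of CDS classes reduced by one —
  a strict assumption that keeps the two units of a binary omega
  combination functionally non-redundant;
* omega count   = alpha1 count x alpha2 count.

An exhaustive enumerator over an explicit part registry backs the census as
its oracle and exposes when the census over-counts (e.g. a grammar-
incompatible part makes the census an upper bound).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product as iproduct
from typing import Optional, Sequence

from .seqmodel import Part

__all__ = [
    "LibraryProfile",
    "AssemblyCensus",
    "CensusWarning",
    "count_census",
    "enumerate_census",
    "induced_profile",
    "DEFAULT_PROFILE",
    "default_profile",
]

#: Default unit anatomy: the core promoter-CDS-terminator pattern. Optional
#: tag/linker/barcode slots can be declared per profile.
CORE_PATTERN: tuple[str, ...] = ("promoter", "CDS", "terminator")


class CensusWarning(UserWarning):
    pass


@dataclass
class LibraryProfile:
    """Per-category counts of functional classes (and optional member counts).

    ``class_counts`` maps a category to its number of functional classes;
    ``members`` optionally maps category -> class name -> member count (used
    only for bookkeeping; the census ignores within-class members).
    ``slot_patterns`` lists the permitted category sequences for one
    alpha-level assembly.
    """

    class_counts: dict[str, int]
    slot_patterns: list[tuple[str, ...]] = field(
        default_factory=lambda: [CORE_PATTERN]
    )
    members: dict[str, dict[str, int]] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        for cat, n in self.class_counts.items():
            if n < 0:
                raise ValueError(f"negative class count for {cat!r}")

    def classes(self, category: str) -> int:
        return self.class_counts.get(category, 0)


@dataclass
class AssemblyCensus:
    n_alpha1: int
    n_alpha2: int
    n_omega: int
    breakdown: dict[int, int] = field(default_factory=dict)  # parts per assembly -> count

    def __post_init__(self) -> None:
        if min(self.n_alpha1, self.n_alpha2, self.n_omega) < 0:
            raise ValueError("census counts must be nonnegative")


def _pattern_count(profile: LibraryProfile, pattern: Sequence[str],
                   cds_reduction: int = 0) -> int:
    total = 1
    for cat in pattern:
        n = profile.classes(cat)
        if cat == "CDS":
            n = max(0, n - cds_reduction)
        total *= n
    return total


def count_census(profile: LibraryProfile) -> AssemblyCensus:
    """Counts of functionally distinct alpha1, alpha2 and omega assemblies."""
    n1 = sum(_pattern_count(profile, pat) for pat in profile.slot_patterns)
    if profile.classes("CDS") == 0:
        warnings.warn(
            "profile has zero CDS classes: the alpha2 count (CDS classes "
            "reduced by one) is undefined and reported as zero",
            CensusWarning,
            stacklevel=2,
        )
        n2 = 0
    else:
        n2 = sum(_pattern_count(profile, pat, cds_reduction=1)
                 for pat in profile.slot_patterns)
    breakdown = {
        len(pat): sum(
            _pattern_count(profile, p) for p in profile.slot_patterns if len(p) == len(pat)
        )
        for pat in profile.slot_patterns
    }
    return AssemblyCensus(n1, n2, n1 * n2, breakdown)


class EnumerationRefused(RuntimeError):
    def __init__(self, lower_bound: int, cap: int):
        super().__init__(
            f"enumeration refused: at least {lower_bound} combinations exceed "
            f"the cap of {cap}"
        )
        self.lower_bound = lower_bound


def enumerate_census(
    library: Sequence[Part],
    slot_patterns: Optional[Sequence[tuple[str, ...]]] = None,
    cap: int = 10_000,
) -> list[tuple[Part, ...]]:
    """Explicitly enumerate the grammar-valid assemblies of a part registry.

    Returns every distinct tuple of parts whose categories follow one of the
    slot patterns and whose grammar codes chain (three_site of each part
    equals five_site of the next). The census equals this list's cardinality
    whenever every part of a category shares the category's grammar slots
    and classes have one member each; otherwise the census is an upper bound.
    """
    slot_patterns = list(slot_patterns or [CORE_PATTERN])
    by_cat: dict[str, list[Part]] = {}
    for p in library:
        by_cat.setdefault(p.category, []).append(p)

    bound = sum(
        math.prod(len(by_cat.get(cat, ())) for cat in pat) for pat in slot_patterns
    )
    if bound > cap:
        raise EnumerationRefused(bound, cap)

    out: list[tuple[Part, ...]] = []
    for pat in slot_patterns:
        pools = [by_cat.get(cat, []) for cat in pat]
        if any(not pool for pool in pools):
            continue
        for combo in iproduct(*pools):
            ok = all(
                combo[i].three_site.code == combo[i + 1].five_site.code
                for i in range(len(combo) - 1)
            )
            if ok:
                out.append(combo)
    return out


def induced_profile(
    library: Sequence[Part],
    slot_patterns: Optional[Sequence[tuple[str, ...]]] = None,
) -> LibraryProfile:
    """The class-count profile implied by an explicit part registry."""
    counts: dict[str, set[str]] = {}
    members: dict[str, dict[str, int]] = {}
    for p in library:
        counts.setdefault(p.category, set()).add(p.functional_class)
        members.setdefault(p.category, {}).setdefault(p.functional_class, 0)
        members[p.category][p.functional_class] += 1
    return LibraryProfile(
        class_counts={cat: len(classes) for cat, classes in counts.items()},
        slot_patterns=list(slot_patterns or [CORE_PATTERN]),
        members=members,
    )


def default_profile() -> LibraryProfile:
    """Profile mirroring the published starter library composition.

    Functional classes: 10 promoters, 28 CDS classes (8 fluorescent
    proteins + 2 luciferases + 2 Cas9s + 13 protein CDSs + 3 drug-resistance
    CDSs), 3 terminators, plus tags/linkers/barcodes available to optional
    slot patterns. With the core pattern this gives 10 x 28 x 3 = 840 alpha1
    units, 810 alpha2 units, and 680,400 omega-level combinations.
    """
    return LibraryProfile(
        class_counts={
            "promoter": 10,
            "CDS": 28,
            "terminator": 3,
            "N-tag": 4,
            "linker": 2,
            "barcode": 1,   # barcodes are functionally interchangeable
            "sgRNA": 1,
        },
        slot_patterns=[CORE_PATTERN],
        name="starter-library",
    )


DEFAULT_PROFILE = default_profile()
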