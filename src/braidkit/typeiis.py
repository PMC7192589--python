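"""Type IIS digestion, sticky-end ligation, and the one-pot cyclic reaction.

The one-pot Golden Gate / GoldenBraid reaction alternates cutting (37 C) and
ligation (16 C) for many thermal cycles; because the desired product has lost
every recognition site of the reaction enzyme while all side products retain
at least one, the cycling enriches the desired product. This module models
that endpoint as a fixed point rather than kinetically: everything cuttable
is cut, every circular closure over compatible overhangs is enumerated, and
the *stable* products are exactly the closures with no remaining recognition
site. The thermocycling protocol itself (25 cycles of 2 min 37 C / 5 min
16 C) is recorded as metadata only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .seqmodel import (
    Backbone,
    DnaMolecule,
    EnzymeSpec,
    Feature,
    Part,
    canonical_seq,
    revcomp,
    sticky_fragment,
)

__all__ = [
    "CutSite",
    "ReactionResult",
    "ReactionError",
    "LigationError",
    "EnumerationCapError",
    "EnumerationCaps",
    "find_sites",
    "digest",
    "ligate",
    "one_pot_reaction",
    "PROTOCOL_METADATA",
]

#: Bench protocol for the one-pot reaction, recorded verbatim but unused by
#: the simulation (the model is a logical fixed point, not kinetics).
PROTOCOL_METADATA = {
    "cycles": 25,
    "cut_step": {"temp_C": 37, "minutes": 2},
    "ligate_step": {"temp_C": 16, "minutes": 5},
    "ligase": "T4 DNA ligase",
}


class ReactionError(RuntimeError):
    """A one-pot reaction cannot produce the desired assembly."""

    def __init__(self, message: str, result: Optional["ReactionResult"] = None):
        super().__init__(message)
        self.result = result


class LigationError(ValueError):
    """Fragments handed to the ligase are not ligatable as required."""


class EnumerationCapError(RuntimeError):
    """Product enumeration exceeded the configured caps."""


@dataclass(frozen=True)
class EnumerationCaps:
    """Guards against combinatorial blow-up on pathological overhang sets."""

    max_fragments_per_product: int = 12
    max_products: int = 10_000


@dataclass(frozen=True)
class CutSite:
    """One type IIS cut: recognition position plus both strand cut points.

    ``top_cut``/``bottom_cut`` are 0-based top-strand coordinates; for every
    modeled enzyme ``bottom_cut = top_cut + 4`` and the released overhang is
    the top-strand 4-mer ``[top_cut, bottom_cut)``. ``cuttable`` is False for
    sites on a linear molecule whose cut window would run off an end.
    """

    enzyme: EnzymeSpec
    strand: str  # "top" | "bottom"
    recog_start: int
    top_cut: int
    bottom_cut: int
    cuttable: bool = True

    def overhang_window(self) -> tuple[int, int]:
        return self.top_cut, self.bottom_cut


def find_sites(
    mol: DnaMolecule,
    enzyme: EnzymeSpec,
    include_uncuttable: bool = False,
) -> list[CutSite]:
    """All recognition occurrences of ``enzyme`` on both strands of ``mol``.

    Circular molecules are scanned across the origin and cut positions are
    reduced modulo length. On linear molecules, sites whose cut window would
    extend past an end are excluded unless ``include_uncuttable`` is set.
    """
    seq = mol.seq
    n = len(seq)
    recog = enzyme.recognition
    m = len(recog)
    if n < m:
        return []
    circular = mol.is_circular
    hay = seq + (seq[: m - 1] if circular else "")
    sites: list[CutSite] = []

    def occurrences(needle: str) -> list[int]:
        found, start = [], 0
        while True:
            i = hay.find(needle, start)
            if i == -1 or i >= n:
                return found
            found.append(i)
            start = i + 1

    for p in occurrences(recog):  # top-strand sites: cut downstream (rightward)
        top = p + m + enzyme.spacer_len
        bottom = top + enzyme.overhang_len
        if circular:
            sites.append(CutSite(enzyme, "top", p, top % n, bottom % n))
        elif bottom <= n:
            sites.append(CutSite(enzyme, "top", p, top, bottom))
        elif include_uncuttable:
            sites.append(CutSite(enzyme, "top", p, top, bottom, cuttable=False))

    for p in occurrences(enzyme.rc_recognition):  # bottom-strand: cut upstream
        top = p - enzyme.spacer_len - enzyme.overhang_len
        bottom = top + enzyme.overhang_len
        if circular:
            sites.append(CutSite(enzyme, "bottom", p, top % n, bottom % n))
        elif top >= 0:
            sites.append(CutSite(enzyme, "bottom", p, top, bottom))
        elif include_uncuttable:
            sites.append(CutSite(enzyme, "bottom", p, top, bottom, cuttable=False))

    sites.sort(key=lambda s: (s.recog_start, s.strand))
    return sites


def _clip_features(mol: DnaMolecule, start: int, end: int) -> list[Feature]:
    """Features of ``mol`` fully inside [start, end), shifted to fragment coords."""
    out = []
    for f in mol.annotations:
        if start <= f.start and f.end <= end:
            out.append(Feature(f.label, f.start - start, f.end - start, f.strand))
    return out


def digest(mol: DnaMolecule, enzyme: EnzymeSpec) -> list[DnaMolecule]:
    """Complete digestion of ``mol`` with one type IIS enzyme.

    A circular parent with k >= 1 sites yields exactly k sticky fragments; a
    linear parent with k sites yields k+1 fragments (outer ends preserved).
    With zero cuttable sites the parent is returned unchanged. Each junction
    leaves complementary 4-nt 5' overhangs on the two flanking fragments.
    """
    sites = [s for s in find_sites(mol, enzyme) if s.cuttable]
    n = len(mol.seq)
    if not mol.is_circular:
        # a cut must fall inside the double-stranded region: recognition
        # sites pointing into an existing sticky end cannot re-cut
        left_ss = 4 if mol.left_end is not None else 0
        right_ss = 4 if mol.right_end is not None else 0
        sites = [
            s for s in sites if s.top_cut >= left_ss and s.bottom_cut <= n - right_ss
        ]
    if not sites:
        return [mol]

    cuts = sorted({s.top_cut for s in sites})
    # overlapping overhang windows cannot both be cut cleanly
    windows = [(c, c + 4) for c in cuts]
    if mol.is_circular:
        pairs = list(zip(windows, windows[1:] + [(windows[0][0] + n, windows[0][1] + n)]))
    else:
        pairs = list(zip(windows, windows[1:]))
    for (a0, a1), (b0, b1) in pairs:
        if b0 < a1:
            raise ReactionError(
                f"overlapping cut windows [{a0},{a1}) and [{b0 % n},{b1 % n}) "
                f"for {enzyme.name} on {mol.name or 'molecule'}"
            )

    frags: list[DnaMolecule] = []
    if mol.is_circular:
        origin = cuts[0]
        rot = mol.rotated(origin)
        rcuts = sorted((c - origin) % n for c in cuts)
        rseq2 = rot.seq + rot.seq
        bounds = rcuts + [n]
        for i in range(len(rcuts)):
            s, e = bounds[i], bounds[i + 1]
            frags.append(
                sticky_fragment(
                    rseq2[s : e + 4],
                    name=f"{mol.name}:frag{i}" if mol.name else f"frag{i}",
                    annotations=_clip_features(rot, s, e + 4),
                )
            )
        return frags

    from .seqmodel import StickyEnd

    bounds = [0] + cuts + [n]
    for i in range(len(bounds) - 1):
        s = bounds[i]
        e = bounds[i + 1] + 4 if bounds[i + 1] != n else n
        seg = mol.seq[s:e]
        left_end = mol.left_end if i == 0 else StickyEnd(seg[:4], "five_prime_top")
        right_end = (
            mol.right_end
            if i == len(bounds) - 2
            else StickyEnd(revcomp(seg[-4:]), "five_prime_bottom")
        )
        frags.append(
            DnaMolecule(
                seq=seg,
                topology="linear",
                left_end=left_end,
                right_end=right_end,
                name=f"{mol.name}:frag{i}" if mol.name else f"frag{i}",
                annotations=_clip_features(mol, s, e),
            )
        )
    return frags


# ---------------------------------------------------------------------------
# ligation


def _ring_seq(path: list[str]) -> str:
    """Circular sequence from an ordered fragment chain (junctions counted once)."""
    return "".join(s[:-4] for s in path)


def _oriented(frag: DnaMolecule) -> list[tuple[str, str, str, int]]:
    """(first4, last4, seq, orientation) for both orientations of a fragment."""
    out = []
    for orient, m in ((1, frag), (-1, frag.reverse_complement())):
        out.append((m.seq[:4], m.seq[-4:], m.seq, orient))
    return out


def _enumerate_cycles(
    frags: Sequence[DnaMolecule],
    caps: EnumerationCaps,
) -> list[tuple[str, frozenset[int]]]:
    """All distinct circular closures over the sticky fragments.

    Each fragment is used at most once per product (no concatemers), both
    orientations are considered, and products are deduplicated under
    canonical rotation. Returns (ring sequence in discovery rotation,
    fragment index set) pairs.
    """
    oriented = [_oriented(f) for f in frags]
    found: dict[str, tuple[str, frozenset[int]]] = {}

    def close_or_extend(anchor: int, path: list[tuple[int, int]], seqs: list[str]) -> None:
        if len(found) >= caps.max_products:
            raise EnumerationCapError(
                f"more than {caps.max_products} circular products; the overhang "
                "set is pathological or the caps need raising"
            )
        last4 = seqs[-1][-4:]
        first4 = seqs[0][:4]
        if last4 == first4:
            ring = _ring_seq(seqs)
            key = canonical_seq(ring)
            if key not in found:
                found[key] = (ring, frozenset(i for i, _ in path))
        if len(path) >= caps.max_fragments_per_product:
            return
        used = {i for i, _ in path}
        for j in range(anchor + 1, len(frags)):
            if j in used:
                continue
            for oi, (f4, _l4, s, _orient) in enumerate(oriented[j]):
                if f4 == last4:
                    path.append((j, oi))
                    seqs.append(s)
                    close_or_extend(anchor, path, seqs)
                    path.pop()
                    seqs.pop()

    for a in range(len(frags)):
        for oi, (_f4, _l4, s, _orient) in enumerate(oriented[a]):
            close_or_extend(a, [(a, oi)], [s])
    return list(found.values())


def ligate(
    frags: Sequence[DnaMolecule],
    caps: EnumerationCaps = EnumerationCaps(),
) -> set[DnaMolecule]:
    """Every distinct circular molecule formable from the given fragments.

    All fragments must be linear with 4-nt 5' overhangs at both ends; each is
    used at most once per product, in either orientation. Products are
    distinct under canonical rotation.
    """
    for f in frags:
        if f.is_circular:
            raise LigationError(f"fragment {f.name!r} is circular, not ligatable")
        if not f.is_sticky:
            raise LigationError(
                f"fragment {f.name!r} has a blunt end; only 4-nt sticky-ended "
                "fragments can close into circles here"
            )
    return {
        DnaMolecule.circular(ring, name="ligation-product")
        for ring, _ in _enumerate_cycles(frags, caps)
    }


# ---------------------------------------------------------------------------
# one-pot reaction

InsertLike = Union[DnaMolecule, Part, Backbone]


@dataclass
class ReactionResult:
    """Outcome of a one-pot digestion-ligation reaction.

    ``stable_products`` are the circular closures with zero remaining
    recognition sites of the reaction enzyme (the species the thermocycling
    enriches). ``desired`` is the unique stable product carrying every
    insert's cargo exactly once on the backbone arm, when it exists.
    ``byproducts`` are notable unstable closures — parental re-closure and
    friends — which re-enter the cut/ligate cycle at the bench and show up as
    blue colonies when they escape.
    """

    stable_products: set[DnaMolecule] = field(default_factory=set)
    desired: Optional[DnaMolecule] = None
    byproducts: set[DnaMolecule] = field(default_factory=set)
    cycle_trace: Optional[list[dict]] = None
    protocol: dict = field(default_factory=lambda: dict(PROTOCOL_METADATA))
    desired_layout: Optional[list[tuple[str, int, int]]] = None


def _as_molecule(obj: InsertLike) -> DnaMolecule:
    if isinstance(obj, Part):
        return obj.cassette()
    if isinstance(obj, Backbone):
        return obj.molecule
    if isinstance(obj, DnaMolecule):
        return obj
    # duck-typed TranscriptionalUnit and friends
    plasmid = getattr(obj, "plasmid", None)
    if isinstance(plasmid, DnaMolecule):
        return plasmid
    raise TypeError(f"cannot interpret {obj!r} as a reaction input")


def _digest_to_fixed_point(
    pool: list[DnaMolecule], enzyme: EnzymeSpec, trace: Optional[list[dict]]
) -> list[DnaMolecule]:
    cycle = 0
    while True:
        nxt: list[DnaMolecule] = []
        changed = False
        for mol in pool:
            pieces = digest(mol, enzyme)
            if len(pieces) > 1 or pieces[0] is not mol:
                changed = changed or len(pieces) > 1 or pieces[0].topology != mol.topology
            nxt.extend(pieces)
        if trace is not None:
            cycle += 1
            trace.append({"cycle": cycle, "species": len(nxt)})
        if not changed or all(
            not [s for s in find_sites(m, enzyme) if s.cuttable] for m in nxt
        ):
            return nxt
        pool = nxt


def _has_site(seq_or_mol: Union[str, DnaMolecule], enzyme: EnzymeSpec) -> bool:
    if isinstance(seq_or_mol, DnaMolecule):
        return bool(find_sites(seq_or_mol, enzyme))
    mol = DnaMolecule.circular(seq_or_mol)
    return bool(find_sites(mol, enzyme))


def one_pot_reaction(
    inserts: Sequence[InsertLike],
    backbone: Backbone,
    enzyme: EnzymeSpec,
    caps: EnumerationCaps = EnumerationCaps(),
    strict: bool = True,
    trace: bool = False,
) -> ReactionResult:
    """Simulate a one-pot type IIS cut-and-ligate reaction.

    ``inserts`` may be :class:`Part` objects (their release cassettes enter
    the pot directly), circular donor plasmids (digested in the pot), or
    linear amplicons carrying enzyme sites in their primer extensions.

    The reaction enzyme must be the backbone's entry enzyme. Returns a
    :class:`ReactionResult`; when no stable product contains every insert's
    cargo, a :class:`ReactionError` naming the first broken junction is
    raised (or, with ``strict=False``, a result with ``desired=None`` is
    returned).
    """
    if enzyme.name != backbone.entry_enzyme.name:
        raise ReactionError(
            f"{enzyme.name} is not the entry enzyme of backbone {backbone.id!r} "
            f"(expected {backbone.entry_enzyme.name})"
        )
    trace_log: Optional[list[dict]] = [] if trace else None

    insert_mols = [_as_molecule(i) for i in inserts]
    pool = insert_mols + [backbone.molecule]
    pieces = _digest_to_fixed_point(pool, enzyme, trace_log)

    sticky = [p for p in pieces if p.is_sticky]
    cycles = _enumerate_cycles(sticky, caps)

    stable: set[DnaMolecule] = set()
    byproducts: set[DnaMolecule] = set()
    for ring, _idx in cycles:
        mol = DnaMolecule.circular(ring)
        if _has_site(mol, enzyme):
            byproducts.add(mol)
        else:
            stable.add(mol)
    # the parental backbone always re-forms from its own two fragments
    byproducts.add(backbone.molecule)

    result = ReactionResult(
        stable_products=stable, byproducts=byproducts, cycle_trace=trace_log
    )

    # -- identify the desired product by walking the grammar chain ----------
    lacz = backbone.lacz_seq
    backbone_frags = digest(backbone.molecule, enzyme)
    arms = [f for f in backbone_frags if lacz not in f.seq]
    if len(backbone_frags) != 2 or len(arms) != 1:
        raise ReactionError(
            f"backbone {backbone.id!r} did not digest into cassette + vector arm "
            f"({len(backbone_frags)} fragments)",
            result,
        )
    arm = arms[0]

    cargo: list[DnaMolecule] = []
    for src in insert_mols:
        frs = _digest_to_fixed_point([src], enzyme, None)
        clean = [
            f
            for f in frs
            if f.is_sticky
            and enzyme.recognition not in f.seq
            and enzyme.rc_recognition not in f.seq
        ]
        if len(clean) != 1:
            msg = (
                f"insert {src.name or '<unnamed>'} yields {len(clean)} "
                f"recognition-free sticky fragments (expected exactly 1 cargo)"
            )
            if strict:
                raise ReactionError(msg, result)
            return result
        cargo.append(clean[0])

    chain: list[DnaMolecule] = []
    remaining = list(cargo)
    code = arm.seq[-4:]
    while remaining:
        matches = [
            (f, o)
            for f in remaining
            for o, m in ((1, f), (-1, f.reverse_complement()))
            if m.seq[:4] == code
        ]
        if not matches:
            msg = (
                f"junction {code} found no partner among remaining inserts "
                f"({', '.join(f.name or '<cargo>' for f in remaining)}); "
                "check the grammar chain"
            )
            if strict:
                raise ReactionError(msg, result)
            return result
        frag, orient = matches[0]
        chosen = frag if orient == 1 else frag.reverse_complement()
        chain.append(chosen)
        remaining.remove(frag)
        code = chosen.seq[-4:]
    if code != arm.seq[:4]:
        msg = (
            f"closing junction mismatch: last insert ends {code} but the vector "
            f"arm expects {arm.seq[:4]}"
        )
        if strict:
            raise ReactionError(msg, result)
        return result

    expected_ring = _ring_seq([arm.seq] + [c.seq for c in chain])
    expected_key = canonical_seq(expected_ring)
    desired = next(
        (m for m in stable if canonical_seq(m.seq) == expected_key), None
    )
    if desired is None:
        msg = "the grammar chain closes but no matching stable product was enumerated"
        if strict:
            raise ReactionError(msg, result)
        return result

    # present the desired product in arm-first rotation with a layout table
    layout: list[tuple[str, int, int]] = []
    pos = 0
    named = DnaMolecule.circular(expected_ring, name="assembly")
    feats: list[Feature] = []
    for piece in [arm] + chain:
        span = len(piece.seq) - 4
        layout.append((piece.name or "fragment", pos, pos + span))
        for f in piece.annotations:
            if f.start >= 0 and pos + f.end <= len(expected_ring):
                feats.append(Feature(f.label, pos + f.start, pos + f.end, f.strand))
        pos += span
    named.annotations = feats
    result.stable_products.discard(desired)
    result.stable_products.add(named)
    result.desired = named
    result.desired_layout = layout
    return result


def brute_force_closures(
    frags: Sequence[DnaMolecule], max_fragments: int = 6
) -> set[str]:
    """Independent oracle: canonical forms of every circular closure.

    Exhaustive search over all subsets, orderings and orientation vectors of
    the fragments — no sharing with the DFS enumeration above. Exponential;
    use on tiny instances only.
    """
    canon: set[str] = set()
    n = len(frags)
    seqs = [f.seq for f in frags]
    for size in range(1, min(n, max_fragments) + 1):
        for combo in itertools.permutations(range(n), size):
            if combo[0] != min(combo):
                continue  # fix rotation of the cycle
            for orients in itertools.product((1, -1), repeat=size):
                parts = [
                    seqs[i] if o == 1 else revcomp(seqs[i])
                    for i, o in zip(combo, orients)
                ]
                ok = all(
                    parts[k][-4:] == parts[(k + 1) % size][:4] for k in range(size)
                )
                if ok:
                    canon.add(canonical_seq(_ring_seq(parts)))
    return canon
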