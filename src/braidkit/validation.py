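"""Predicted bench-validation readouts.

Three in-silico counterparts of the wet-lab checks used to confirm
GoldenBraid products: restriction-enzyme fingerprints (fragment sizes of a
complete digest), blue/white colony screening (presence or loss of the
backbone's lacZ drop-out cassette), and sequence-level verification of an
assembly against its design (the stand-in for Sanger confirmation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .seqmodel import Backbone, DnaMolecule, Part, canonical_seq, revcomp
from .typeiis import find_sites

__all__ = [
    "Fingerprint",
    "VerificationReport",
    "fingerprint",
    "predict_screen",
    "verify_assembly",
    "gel_text",
]

#: Minimum match length (nt) for a lacZ remnant to count as "partially present".
PARTIAL_LACZ_MIN = 30


@dataclass
class Fingerprint:
    enzymes: tuple[str, ...]
    fragment_lengths: list[int]
    topology_note: str

    def __post_init__(self) -> None:
        if not self.fragment_lengths:
            raise ValueError("a fingerprint has at least one fragment")


def fingerprint(mol: DnaMolecule, enzymes: Sequence) -> Fingerprint:
    """Fragment sizes of a simultaneous complete digest, sorted descending.

    Fragment lengths are the distances between successive top-strand cut
    positions, so they always sum to the molecule length. A circular
    molecule with no cuts is reported as a single full-length species.
    """
    n = len(mol.seq)
    cuts = sorted(
        {s.top_cut for enz in enzymes for s in find_sites(mol, enz) if s.cuttable}
    )
    names = tuple(e.name for e in enzymes)
    if not cuts:
        note = "uncut circular" if mol.is_circular else "uncut linear"
        return Fingerprint(names, [n], note)
    if mol.is_circular:
        lengths = [
            (cuts[(i + 1) % len(cuts)] - cuts[i]) % n or n for i in range(len(cuts))
        ]
        note = f"circular, {len(cuts)} cuts"
    else:
        bounds = [0] + cuts + [n]
        lengths = [bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)]
        lengths = [x for x in lengths if x > 0]
        note = f"linear, {len(cuts)} cuts"
    return Fingerprint(names, sorted(lengths, reverse=True), note)


def gel_text(fp: Fingerprint, width: int = 40) -> str:
    """A text gel schematic: one band per fragment, migration ~ -log(size)."""
    import math

    if not fp.fragment_lengths:
        return "(no fragments)"
    lo = max(min(fp.fragment_lengths), 1)
    hi = max(fp.fragment_lengths)
    lines = [f"digest: {'+'.join(fp.enzymes)} ({fp.topology_note})"]
    for size in fp.fragment_lengths:
        if hi == lo:
            pos = 0
        else:
            pos = int(width * (math.log(hi) - math.log(size)) / (math.log(hi) - math.log(lo)))
        lines.append(" " * pos + f"== {size} bp")
    return "\n".join(lines)


def predict_screen(product: DnaMolecule, backbone: Backbone) -> str:
    """Blue/white screening outcome for a circular product.

    ``blue`` when the backbone's intact lacZ cassette is present (parental
    re-closure), ``white`` when it is fully absent (the cassette dropped
    out), ``indeterminate`` when a fragment of at least
    :data:`PARTIAL_LACZ_MIN` nt remains.
    """
    if not product.is_circular:
        raise ValueError("screening is defined for circular products")
    lacz = backbone.lacz_seq
    hay = product.seq + product.seq[: len(lacz)]
    hay_rc = revcomp(product.seq) + revcomp(product.seq)[: len(lacz)]
    if lacz in hay or lacz in hay_rc:
        return "blue"
    k = PARTIAL_LACZ_MIN
    if len(lacz) >= k:
        probes = {lacz[i : i + k] for i in range(0, len(lacz) - k + 1)}
        for probe in probes:
            if probe in hay or probe in hay_rc:
                return "indeterminate"
    return "white"


@dataclass
class VerificationReport:
    passed: bool
    part_status: dict[str, str] = field(default_factory=dict)  # found-in-order/missing/misordered
    notes: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


def verify_assembly(
    product: DnaMolecule,
    expected_parts: Sequence[Part],
    backbone: Backbone,
    expected_product: DnaMolecule | None = None,
) -> VerificationReport:
    """Check a circular product against its design.

    Each expected part must occur exactly once, in order, downstream of the
    backbone's vector-arm sequence; unexpected sequence between parts beyond
    the 4-nt grammar junctions is noted. When ``expected_product`` is given,
    the report passes only if the product equals it under canonical rotation.
    """
    if not product.is_circular:
        raise ValueError("verification is defined for circular products")
    report = VerificationReport(passed=True)

    # orient the product so the backbone core reads forward from the origin
    probe = backbone.molecule.seq[-200:]  # tail of the core region
    oriented = None
    for cand in (product, product.reverse_complement()):
        hay = cand.seq + cand.seq
        i = hay.find(probe)
        if i != -1:
            oriented = cand.rotated((i + len(probe)) % len(cand.seq))
            break
    if oriented is None:
        report.passed = False
        report.notes.append("backbone arm sequence not found in product")
        oriented = product

    hay = oriented.seq + oriented.seq
    positions: dict[str, int] = {}
    for part in expected_parts:
        needle = part.insert.seq
        i = hay.find(needle)
        if i == -1 or i >= len(oriented.seq):
            report.part_status[part.id] = "missing"
            report.passed = False
        else:
            positions[part.id] = i
            report.part_status[part.id] = "found"

    found_ids = [p.id for p in expected_parts if p.id in positions]
    in_order = sorted(found_ids, key=lambda pid: positions[pid])
    for pid in found_ids:
        if in_order.index(pid) != found_ids.index(pid):
            report.part_status[pid] = "misordered"
            report.passed = False
        elif report.part_status[pid] == "found":
            report.part_status[pid] = "found-in-order"

    # unexpected sequence between consecutive parts (beyond 4-nt junctions)
    ordered = [pid for pid in in_order]
    for a, b in zip(ordered, ordered[1:]):
        pa = positions[a] + len(next(p for p in expected_parts if p.id == a).insert.seq)
        gap = positions[b] - pa
        if gap > 4:
            report.notes.append(f"{gap} nt of unexpected sequence between {a} and {b}")

    if expected_product is not None:
        if canonical_seq(product.seq) != canonical_seq(expected_product.seq):
            report.passed = False
            report.notes.append("product differs from the predicted construct")
    return report
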