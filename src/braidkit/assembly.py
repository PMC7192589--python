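"""The GoldenBraid planner: grammar-chain validation, alpha-level multipartite
assembly, omega-level combination of 2-5 units, and iterative alpha<->omega
braid planning.

The braid alternates enzymes by level: parts enter alpha backbones with BsaI,
alpha-level transcriptional units enter omega backbones with BsmBI, two
omega-level inserts re-enter an alpha backbone with BsaI, and so on until
vector capacity becomes limiting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .seqmodel import (
    Backbone,
    DnaMolecule,
    GrammarError,
    GrammarSite,
    Part,
)
from .enzymes import BSAI, BSMBI
from .typeiis import EnumerationCaps, ReactionResult, one_pot_reaction

__all__ = [
    "JunctionFault",
    "TranscriptionalUnit",
    "PlanStep",
    "BraidPlan",
    "validate_chain",
    "assemble_alpha",
    "assemble_omega",
    "plan_braid",
    "execute_plan",
    "OMEGA_MIN_UNITS",
    "OMEGA_MAX_UNITS",
]

#: Design rule: 2-5 alpha-level units may be combined into one omega backbone.
OMEGA_MIN_UNITS = 2
OMEGA_MAX_UNITS = 5

#: Soft capacity threshold (bp) beyond which a plan carries a warning; the
#: braid can iterate "until vector capacity becomes limiting".
DEFAULT_CAPACITY_BP = 50_000


@dataclass(frozen=True)
class JunctionFault:
    """One failing junction in a grammar chain."""

    index: int          # junction index: -1 = backbone|first part
    left: str           # code offered from the left
    right: str          # code expected on the right
    description: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.description


@dataclass
class TranscriptionalUnit:
    """An assembled alpha-level unit: ordered parts plus the product plasmid.

    ``unit_sites`` are the grammar codes the unit exposes for the next BsmBI
    round — conferred by the alpha backbone it was assembled in.
    """

    parts: list[Part]
    plasmid: DnaMolecule
    level: str
    unit_sites: tuple[GrammarSite, GrammarSite]
    id: str = ""

    def __post_init__(self) -> None:
        if not self.level.startswith("alpha"):
            raise ValueError(f"transcriptional units live at alpha levels, not {self.level!r}")
        if not self.id:
            self.id = "+".join(p.id for p in self.parts) or "unit"


@dataclass(frozen=True)
class PlanStep:
    """One reaction in a braid plan."""

    level: str                 # "alpha" | "omega" | "alpha-combine"
    enzyme: str                # "BsaI" | "BsmBI"
    backbone_id: str
    inputs: tuple[str, ...]    # ids of parts / earlier outputs
    output_id: str


@dataclass
class BraidPlan:
    steps: list[PlanStep]
    target: list[list[str]]                 # unit descriptors (part-id lists)
    final_output: str = ""
    warnings: list[str] = field(default_factory=list)

    def enzymes_alternate(self) -> bool:
        """Along every dependency chain, consecutive reactions alternate enzymes."""
        producer = {s.output_id: s for s in self.steps}
        for step in self.steps:
            for inp in step.inputs:
                parent = producer.get(inp)
                if parent is not None and parent.enzyme == step.enzyme:
                    return False
        return True


def validate_chain(
    parts: Sequence[Part], backbone: Backbone
) -> list[JunctionFault]:
    """Check that the parts' grammar codes chain and close on the backbone arm.

    Returns an empty list when the chain is valid; otherwise one fault per
    failing junction. The grammar codes, not the category labels, are
    authoritative.
    """
    if not parts:
        raise ValueError("empty chain: at least one part is required")
    faults: list[JunctionFault] = []
    left_flank, right_flank = backbone.flank_sites
    if parts[0].five_site.code != left_flank.code:
        faults.append(
            JunctionFault(
                -1,
                left_flank.code,
                parts[0].five_site.code,
                f"backbone arm offers {left_flank.code} but first part "
                f"{parts[0].id!r} starts with {parts[0].five_site.code}",
            )
        )
    for i in range(len(parts) - 1):
        a, b = parts[i], parts[i + 1]
        if a.three_site.code != b.five_site.code:
            faults.append(
                JunctionFault(
                    i,
                    a.three_site.code,
                    b.five_site.code,
                    f"junction {i}: {a.id!r} ends {a.three_site.code} but "
                    f"{b.id!r} starts {b.five_site.code}",
                )
            )
    if parts[-1].three_site.code != right_flank.code:
        faults.append(
            JunctionFault(
                len(parts) - 1,
                parts[-1].three_site.code,
                right_flank.code,
                f"last part {parts[-1].id!r} ends {parts[-1].three_site.code} "
                f"but the backbone arm closes with {right_flank.code}",
            )
        )
    return faults


def assemble_alpha(
    parts: Sequence[Part],
    backbone: Backbone,
    caps: EnumerationCaps = EnumerationCaps(),
) -> TranscriptionalUnit:
    """Multipartite BsaI assembly of parts into an alpha-level backbone."""
    if not parts:
        raise ValueError("empty chain: an alpha assembly needs at least one part")
    if not backbone.level.startswith("alpha"):
        raise ValueError(
            f"assemble_alpha needs an alpha-level backbone, got {backbone.level!r}"
        )
    faults = validate_chain(parts, backbone)
    if faults:
        raise GrammarError(
            "grammar chain invalid: " + "; ".join(f.description for f in faults)
        )
    result = one_pot_reaction(list(parts), backbone, BSAI, caps=caps)
    assert result.desired is not None
    if backbone.unit_sites is None:
        raise ValueError(f"alpha backbone {backbone.id!r} lacks unit_sites")
    return TranscriptionalUnit(
        parts=list(parts),
        plasmid=result.desired,
        level=backbone.level,
        unit_sites=backbone.unit_sites,
    )


def assemble_omega(
    units: Sequence[TranscriptionalUnit],
    backbone: Backbone,
    caps: EnumerationCaps = EnumerationCaps(),
) -> DnaMolecule:
    """BsmBI combination of 2-5 alpha-level units into an omega backbone.

    The bound is a design rule of the braid; counts outside [2, 5] are
    refused. Each unit's cargo appears exactly once, in chain order, and the
    product carries the omega tier's chloramphenicol marker metadata.
    """
    if not (OMEGA_MIN_UNITS <= len(units) <= OMEGA_MAX_UNITS):
        raise ValueError(
            f"{len(units)} units: an omega combination takes between "
            f"{OMEGA_MIN_UNITS} and {OMEGA_MAX_UNITS} alpha-level units"
        )
    if not backbone.level.startswith("omega"):
        raise ValueError(
            f"assemble_omega needs an omega-level backbone, got {backbone.level!r}"
        )
    left_flank, right_flank = backbone.flank_sites
    faults = []
    if units[0].unit_sites[0].code != left_flank.code:
        faults.append(
            f"omega arm offers {left_flank.code} but unit 1 starts "
            f"{units[0].unit_sites[0].code}"
        )
    for i in range(len(units) - 1):
        a, b = units[i], units[i + 1]
        if a.unit_sites[1].code != b.unit_sites[0].code:
            faults.append(
                f"unit junction {i}: {a.id!r} ends {a.unit_sites[1].code} but "
                f"{b.id!r} starts {b.unit_sites[0].code}"
            )
    if units[-1].unit_sites[1].code != right_flank.code:
        faults.append(
            f"last unit ends {units[-1].unit_sites[1].code} but the omega arm "
            f"closes with {right_flank.code}"
        )
    if faults:
        raise GrammarError("unit chain invalid: " + "; ".join(faults))
    result = one_pot_reaction(list(units), backbone, BSMBI, caps=caps)
    assert result.desired is not None
    product = result.desired
    product.name = f"omega:{'+'.join(u.id for u in units)}"
    return product


# ---------------------------------------------------------------------------
# braid planning


def _group_sizes(n: int) -> list[int]:
    """Greedy left-to-right packing into omega groups of <= 5 units.

    When more than one group is needed, the group count is padded to an even
    number so the following alpha round can pair omega inserts two by two.
    """
    if n <= OMEGA_MAX_UNITS:
        return [n]
    import math

    g = math.ceil(n / OMEGA_MAX_UNITS)
    if g % 2:
        g += 1
    base, extra = divmod(n, g)
    sizes = [base + (1 if i < extra else 0) for i in range(g)]
    if min(sizes) < OMEGA_MIN_UNITS:
        raise ValueError(f"cannot pack {n} units into balanced omega groups of 2-5")
    return sizes


def plan_braid(
    target: Sequence[Sequence[str]],
    library: dict[str, Part],
    kit: "BackboneKit",
    capacity_bp: int = DEFAULT_CAPACITY_BP,
) -> BraidPlan:
    """Plan the reactions that build ``target`` (an ordered list of unit
    descriptors, each an ordered list of part ids) into one final construct.

    The plan is minimal-depth under greedy packing: assemble every unit at
    the alpha level, pack units into omega reactions of <= 5, then alternate
    alpha (binary) and omega rounds until one construct remains.
    """
    for unit in target:
        for pid in unit:
            if pid not in library:
                raise KeyError(f"part {pid!r} not found in the library")
    steps: list[PlanStep] = []
    warnings: list[str] = []
    n = len(target)
    if n == 0:
        raise ValueError("empty target")

    est_size = sum(
        sum(len(library[pid].insert.seq) + 4 for pid in unit) for unit in target
    ) + 3000
    if est_size > capacity_bp:
        warnings.append(
            f"estimated construct size ~{est_size} bp exceeds the configured "
            f"capacity threshold ({capacity_bp} bp): vector capacity may become limiting"
        )

    if n == 1:
        bb = kit.alpha_series(1)[0]
        step = PlanStep(
            "alpha", "BsaI", bb.id, tuple(target[0]), "TU1"
        )
        return BraidPlan([step], [list(u) for u in target], final_output="TU1",
                         warnings=warnings)

    # alpha round: one TU per descriptor, positioned within its omega group
    sizes = _group_sizes(n)
    unit_ids: list[str] = []
    idx = 0
    group_inputs: list[list[str]] = []
    for gi, size in enumerate(sizes):
        alphas = kit.alpha_series(size)
        ids = []
        for pos in range(size):
            uid = f"TU{idx + 1}"
            steps.append(
                PlanStep("alpha", "BsaI", alphas[pos].id, tuple(target[idx]), uid)
            )
            ids.append(uid)
            idx += 1
        group_inputs.append(ids)
        unit_ids.extend(ids)

    # omega round(s) + binary alpha-combine rounds until a single product
    level = 0
    current = group_inputs
    out_counter = 0
    while True:
        omega_ids = []
        for gi, ids in enumerate(current):
            out_counter += 1
            oid = f"OM{out_counter}"
            bb = kit.omega_for_parity(gi % 2)
            steps.append(PlanStep("omega", "BsmBI", bb.id, tuple(ids), oid))
            omega_ids.append(oid)
        if len(omega_ids) == 1:
            return BraidPlan(steps, [list(u) for u in target],
                             final_output=omega_ids[0], warnings=warnings)
        # binary alpha combinations of omega inserts
        alpha_ids = []
        pair_count = len(omega_ids) // 2
        alphas = kit.alpha_series(pair_count) if pair_count > 1 else [kit.alpha_series(1)[0]]
        for pi in range(pair_count):
            out_counter += 1
            aid = f"AC{out_counter}"
            steps.append(
                PlanStep(
                    "alpha-combine",
                    "BsaI",
                    alphas[pi].id,
                    (omega_ids[2 * pi], omega_ids[2 * pi + 1]),
                    aid,
                )
            )
            alpha_ids.append(aid)
        if len(alpha_ids) == 1:
            return BraidPlan(steps, [list(u) for u in target],
                             final_output=alpha_ids[0], warnings=warnings)
        # regroup the combined alpha products for the next omega round
        sizes2 = _group_sizes(len(alpha_ids))
        current, i0 = [], 0
        for s in sizes2:
            current.append(alpha_ids[i0 : i0 + s])
            i0 += s
        level += 1
        if level > 8:  # pragma: no cover - safety valve
            raise RuntimeError("braid plan failed to converge")


def execute_plan(
    plan: BraidPlan,
    library: dict[str, Part],
    kit: "BackboneKit",
    caps: EnumerationCaps = EnumerationCaps(),
) -> dict[str, object]:
    """Run every step of a braid plan through the simulator.

    Returns a mapping of output ids to products; ``plan.final_output`` keys
    the final construct.
    """
    products: dict[str, object] = {}
    backbones = kit.by_id()

    def resolve(name: str):
        if name in products:
            return products[name]
        return library[name]

    for step in plan.steps:
        bb = backbones[step.backbone_id]
        inputs = [resolve(i) for i in step.inputs]
        if step.level == "alpha":
            products[step.output_id] = assemble_alpha(inputs, bb, caps=caps)
        elif step.level == "omega":
            products[step.output_id] = assemble_omega(inputs, bb, caps=caps)
        elif step.level == "alpha-combine":
            mols = [
                p.plasmid if isinstance(p, TranscriptionalUnit) else p for p in inputs
            ]
            result: ReactionResult = one_pot_reaction(mols, bb, BSAI, caps=caps)
            assert result.desired is not None
            # the combined product is itself alpha-level: it can re-enter omega
            products[step.output_id] = TranscriptionalUnit(
                parts=[], plasmid=result.desired, level=bb.level,
                unit_sites=bb.unit_sites, id=step.output_id,
            )
        else:  # pragma: no cover - defensive
            raise ValueError(f"unknown step level {step.level!r}")
    return products


# imported late to avoid a circular import at module load
from .backbones import BackboneKit  # noqa: E402
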