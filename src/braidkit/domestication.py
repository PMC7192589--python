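"""Part domestication: turning a raw sequence into a GoldenBraid-ready part.

Domestication does three things:

1. **Internal site removal.** Any BsaI/BsmBI recognition inside the part
   would be cut during assembly, so each internal site is destroyed by a
   single-base substitution — synonymous when the part is a CDS, chosen to
   maximize the usage frequency of the resulting codon. When a part carries
   internal sites it is amplified as *patches*: multiple PCR pieces that
   re-ligate at 4-nt junctions placed at the destroyed sites, with the
   mutation carried on the junction primers.
2. **Grammar tagging.** Terminal primers add the entry-enzyme (BsmBI)
   recognition, the pUPD2 universal ends, the assembly-level BsaI sites and
   the part's 4-bp grammar codes as 5' extensions.
3. **Head codon optimization.** For CDSs not already codon-adapted, the
   first ~10 codons (the stretch that matters most for expression in this
   organism) are rewritten to the most-used synonymous codons, skipping any
   rewrite that would create a new restriction site.

The predicted entry clone is obtained by actually simulating the one-pot
BsmBI reaction of the patch amplicons with pUPD2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.SeqUtils import MeltingTemp

from .codon import CodonTable, GENETIC_CODE, SYNONYMS, default_usage, translate
from .enzymes import BSAI, BSMBI
from .grammar import DEFAULT_GRAMMAR, ENTRY_JUNCTIONS
from .seqmodel import DnaMolecule, GrammarSet, Part, revcomp
from .typeiis import CutSite, find_sites, one_pot_reaction

__all__ = [
    "DomesticationError",
    "Mutation",
    "Patch",
    "PrimerPair",
    "Primer",
    "DomesticationPlan",
    "scan_internal",
    "silent_fix",
    "optimize_head",
    "domesticate",
    "primer_sheet",
]

#: Elements shorter than this are ordered as annealed complementary oligos
#: rather than PCR-amplified.
SHORT_ELEMENT_THRESHOLD = 100

_SPACER = "A"


class DomesticationError(RuntimeError):
    """A raw sequence cannot be domesticated under the current rules."""


@dataclass(frozen=True)
class Mutation:
    position: int
    ref: str
    alt: str
    rationale: str = ""


@dataclass
class Patch:
    """One PCR piece of a patched part.

    ``span`` is half-open on the (mutated) raw sequence; consecutive patches
    overlap by the 4-nt junction so that ligation reconstructs the sequence
    with each junction counted once.
    """

    span: tuple[int, int]
    junction_left: Optional[str]    # 4-nt code at the left boundary (None = part 5')
    junction_right: Optional[str]   # 4-nt code at the right boundary (None = part 3')
    mutations: list[Mutation] = field(default_factory=list)


@dataclass
class Primer:
    name: str
    extension: str      # 5' non-template addition (enzyme + spacer + code [+ mutation])
    anneal: str         # template-matching 3' segment
    tm_anneal: float    # nearest-neighbor Tm of the annealing segment, deg C

    @property
    def sequence(self) -> str:
        return self.extension + self.anneal


@dataclass
class PrimerPair:
    forward: Primer
    reverse: Primer


@dataclass
class DomesticationPlan:
    part_id: str
    patches: list[Patch]
    primers: list[PrimerPair]
    predicted_entry_clone: DnaMolecule
    codon_changes: list[tuple[int, str, str]]
    part: Part
    mutations: list[Mutation]
    amplicons: list[DnaMolecule]
    short_synthesis: bool = False


def scan_internal(
    raw: DnaMolecule, enzymes: Sequence = (BSAI, BSMBI)
) -> list[CutSite]:
    """Every recognition occurrence of the given enzymes, both strands.

    Unlike :func:`braidkit.typeiis.find_sites` with default flags, sites
    whose cut window runs off the molecule are included — domestication cares
    about the recognition sequence itself, not whether this particular
    molecule could be cut.
    """
    sites: list[CutSite] = []
    for enz in enzymes:
        sites.extend(find_sites(raw, enz, include_uncuttable=True))
    sites.sort(key=lambda s: s.recog_start)
    return sites


def _recognition_span(site: CutSite) -> tuple[int, int]:
    return site.recog_start, site.recog_start + len(site.enzyme.recognition)


def _window_clean(seq: str, lo: int, hi: int, avoid: Sequence) -> bool:
    """No recognition of any avoided enzyme within seq[lo:hi], both strands."""
    window = seq[max(0, lo) : hi]
    for enz in avoid:
        if enz.recognition in window or enz.rc_recognition in window:
            return False
    return True


def silent_fix(
    raw: DnaMolecule,
    site: CutSite,
    usage: Optional[CodonTable] = None,
    is_cds: bool = True,
    avoid: Sequence = (BSAI, BSMBI),
) -> Mutation:
    """One single-base substitution that destroys ``site``'s recognition.

    For a CDS (reading frame from position 0) the substitution is synonymous
    and, among all destroying synonymous candidates, maximizes the codon
    usage frequency of the new codon. For non-CDS parts, the first
    substitution inside the recognition hexamer that destroys the site
    without creating a new one is returned.
    """
    usage = usage or default_usage()
    seq = raw.seq
    lo, hi = _recognition_span(site)

    def destroyed_and_clean(newseq: str) -> bool:
        # the original occurrence must be gone and no new site created nearby
        return _window_clean(newseq, lo - 6, hi + 6, avoid)

    if not is_cds:
        for pos in range(lo, hi):
            for base in "ACGT":
                if base == seq[pos]:
                    continue
                cand = seq[:pos] + base + seq[pos + 1 :]
                if destroyed_and_clean(cand):
                    return Mutation(pos, seq[pos], base, "non-coding substitution")
        raise DomesticationError(
            f"no single substitution inside [{lo},{hi}) destroys the "
            f"{site.enzyme.name} site without creating another"
        )

    best: Optional[tuple[float, int, str, Mutation]] = None
    first_codon = lo // 3
    last_codon = (hi - 1) // 3
    for ci in range(first_codon, last_codon + 1):
        cstart = 3 * ci
        codon = seq[cstart : cstart + 3]
        if len(codon) < 3:
            continue
        aa = GENETIC_CODE[codon]
        for alt_codon in SYNONYMS[aa]:
            diffs = [k for k in range(3) if alt_codon[k] != codon[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            pos = cstart + k
            if not (lo <= pos < hi):
                continue  # the change must hit the recognition hexamer
            cand = seq[:pos] + alt_codon[k] + seq[pos + 1 :]
            if not destroyed_and_clean(cand):
                continue
            score = (usage.fraction(alt_codon), -pos, alt_codon)
            mut = Mutation(
                pos,
                seq[pos],
                alt_codon[k],
                f"synonymous {codon}->{alt_codon} ({aa}), usage "
                f"{usage.fraction(alt_codon):.2f}",
            )
            if best is None or score > best[:3]:
                best = (*score, mut)
    if best is None:
        raise DomesticationError(
            f"undomesticatable {site.enzyme.name} site at [{lo},{hi}): no "
            "synonymous single-base substitution destroys it; a two-codon "
            "rewrite would be needed (not automated)"
        )
    return best[3]


def optimize_head(
    cds: DnaMolecule,
    usage: Optional[CodonTable] = None,
    n_codons: int = 10,
    avoid: Sequence = (BSAI, BSMBI),
    force: bool = False,
) -> tuple[DnaMolecule, list[tuple[int, str, str]]]:
    """Rewrite the first ``n_codons`` codons to the most-used synonyms.

    Translation is unchanged. A replacement that would create a recognition
    site of an avoided enzyme falls back to the next-ranked codon (and
    ultimately keeps the original codon). A CDS without a start codon is
    left untouched with a warning unless ``force`` is set.
    """
    usage = usage or default_usage()
    seq = cds.seq
    if not seq.startswith("ATG") and not force:
        warnings.warn(
            f"{cds.name or 'CDS'} does not start with ATG; head left unchanged",
            stacklevel=2,
        )
        return cds, []
    n = min(n_codons, len(seq) // 3)
    changes: list[tuple[int, str, str]] = []
    out = list(seq)
    for ci in range(n):
        cstart = 3 * ci
        codon = "".join(out[cstart : cstart + 3])
        aa = GENETIC_CODE[codon]
        for candidate in usage.ranked_synonyms(aa):
            if candidate == codon:
                break  # current codon is the best remaining choice
            trial = out[:]
            trial[cstart : cstart + 3] = candidate
            if _window_clean("".join(trial), cstart - 6, cstart + 9, avoid):
                out[cstart : cstart + 3] = candidate
                changes.append((ci, codon, candidate))
                break
    new = DnaMolecule.linear("".join(out), name=cds.name)
    assert translate(new.seq) == translate(seq)
    return new, changes


# ---------------------------------------------------------------------------
# primer and amplicon construction


def _fix_boundary_sites(
    final: str,
    five_code: str,
    three_code: str,
    is_cds: bool,
    usage: CodonTable,
    avoid: Sequence,
) -> tuple[str, list[Mutation]]:
    """Destroy recognition sites that only exist in the flanked context.

    A site can span the junction between a grammar code and the insert (or
    the insert and the downstream constant region); such sites are invisible
    to an insert-only scan but would be cut during assembly. The fix is a
    substitution at an insert position inside the spanning recognition —
    synonymous for CDS parts — carried on the terminal primer.
    """
    mutations: list[Mutation] = []
    left_const = BSAI.recognition + _SPACER + five_code
    right_const = three_code + _SPACER + BSAI.rc_recognition
    off = len(left_const)  # insert position p sits at ctx position off + p

    def hits_of(insert: str) -> list[tuple[int, str]]:
        ctx = left_const + insert + right_const
        designed = {0, len(ctx) - 6}
        found = []
        for enz in avoid:
            for needle in (enz.recognition, enz.rc_recognition):
                start = 0
                while True:
                    i = ctx.find(needle, start)
                    if i == -1:
                        break
                    if i not in designed:
                        found.append((i, enz.name))
                    start = i + 1
        return sorted(found)

    def substitutions_at(p_insert: int) -> list[str]:
        """Legal replacement bases at an insert position (synonymous for CDS)."""
        if not is_cds:
            return [b for b in "ACGT" if b != final[p_insert]]
        ci = p_insert // 3
        codon = final[3 * ci : 3 * ci + 3]
        if len(codon) < 3:
            return []
        k = p_insert - 3 * ci
        out = []
        for alt_codon in SYNONYMS[GENETIC_CODE[codon]]:
            diffs = [j for j in range(3) if alt_codon[j] != codon[j]]
            if diffs == [k]:
                out.append(alt_codon[k])
        return out

    for _round in range(20):
        hits = hits_of(final)
        if not hits:
            return final, mutations
        lo, enz_name = hits[0]
        fixed = False
        for p in range(max(lo, off), min(lo + 6, off + len(final))):
            for base in substitutions_at(p - off):
                cand = final[: p - off] + base + final[p - off + 1 :]
                if len(hits_of(cand)) < len(hits):
                    note = "boundary %s site%s" % (
                        enz_name, ", synonymous" if is_cds else ""
                    )
                    mutations.append(Mutation(p - off, final[p - off], base, note))
                    final = cand
                    fixed = True
                    break
            if fixed:
                break
        if not fixed:
            raise DomesticationError(
                f"cannot destroy a {enz_name} site spanning the grammar "
                f"junction at context position {lo}"
            )
    raise DomesticationError("boundary site removal did not converge")


def _pick_anneal(template: str, min_len: int = 18, max_len: int = 35,
                 tm_target: float = 60.0) -> str:
    """Shortest >= min_len prefix of ``template`` with Tm >= tm_target."""
    limit = min(max_len, len(template))
    for k in range(min_len, limit + 1):
        seg = template[:k]
        if MeltingTemp.Tm_NN(seg) >= tm_target:
            return seg
    return template[:limit]


def _terminal_fwd_extension(five_code: str) -> str:
    return (
        BSMBI.recognition + _SPACER + ENTRY_JUNCTIONS["E5"]
        + BSAI.recognition + _SPACER + five_code
    )


def _terminal_rev_extension(three_code: str) -> str:
    # reverse primer 5'->3' on the bottom strand; appears on the top strand as
    # three_code a GAGACC E3 a GAGACG
    return (
        BSMBI.recognition + revcomp(_SPACER) + revcomp(ENTRY_JUNCTIONS["E3"])
        + BSAI.recognition + revcomp(_SPACER) + revcomp(three_code)
    )


def _amplicon_seq(
    final: str,
    span: tuple[int, int],
    is_first: bool,
    is_last: bool,
    five_code: str,
    three_code: str,
) -> str:
    s, e = span
    head = (
        BSMBI.recognition + _SPACER + ENTRY_JUNCTIONS["E5"]
        + BSAI.recognition + _SPACER + five_code
        if is_first
        else BSMBI.recognition + _SPACER
    )
    tail = (
        three_code + _SPACER + BSAI.rc_recognition
        + ENTRY_JUNCTIONS["E3"] + _SPACER + BSMBI.rc_recognition
        if is_last
        else _SPACER + BSMBI.rc_recognition
    )
    if is_last:
        return head + final[s:e] + tail
    return head + final[s:e] + tail


def domesticate(
    raw: DnaMolecule,
    category: str,
    grammar: Optional[GrammarSet] = None,
    usage: Optional[CodonTable] = None,
    part_id: Optional[str] = None,
    n_codons: int = 10,
    optimize: Optional[bool] = None,
    short_threshold: int = SHORT_ELEMENT_THRESHOLD,
    pupd2=None,
    avoid: Sequence = (BSAI, BSMBI),
    functional_class: str = "",
) -> DomesticationPlan:
    """Full domestication of a raw linear sequence into an entry clone.

    Produces patches (internal site count + 1), two primers per patch, the
    applied mutations and head-codon changes, and the predicted entry clone
    obtained by simulating the one-pot BsmBI reaction of the reconstructed
    patch amplicons with pUPD2.
    """
    if raw.topology != "linear":
        raise ValueError("domestication starts from a linear raw sequence")
    grammar = grammar or DEFAULT_GRAMMAR
    usage = usage or default_usage()
    five_site, three_site = grammar.sites_for_category(category)
    part_id = part_id or (raw.name or "part")
    is_cds = category == "CDS"
    if optimize is None:
        optimize = is_cds

    work = raw
    codon_changes: list[tuple[int, str, str]] = []
    if is_cds and optimize:
        work, codon_changes = optimize_head(work, usage, n_codons=n_codons, avoid=avoid)

    # iteratively destroy internal sites (a fix can, rarely, expose a new one)
    mutations: list[Mutation] = []
    seq = work.seq
    for _round in range(50):
        sites = scan_internal(DnaMolecule.linear(seq), avoid)
        if not sites:
            break
        mut = silent_fix(
            DnaMolecule.linear(seq), sites[0], usage, is_cds=is_cds, avoid=avoid
        )
        seq = seq[: mut.position] + mut.alt + seq[mut.position + 1 :]
        mutations.append(mut)
    else:  # pragma: no cover - defensive
        raise DomesticationError(f"{part_id}: site removal did not converge")
    final = seq

    # sites that only exist in the flanked context (spanning a grammar code
    # and the insert) are destroyed via the terminal primers, not patches
    final, boundary_mutations = _fix_boundary_sites(
        final, five_site.code, three_site.code, is_cds, usage, avoid
    )

    # patch junctions: the 4 nt immediately 5' of each mutated base, slid by
    # up to +/-6 nt to avoid collisions with grammar codes or other junctions
    reserved = set(grammar.codes()) | {revcomp(c) for c in grammar.codes()}
    junctions: list[tuple[int, str]] = []
    for mut in sorted(mutations, key=lambda m: m.position):
        placed = False
        for delta in (0, -1, 1, -2, 2, -3, 3, -4, 4, -5, 5, -6, 6):
            w = mut.position - 4 + delta
            if w < 4 or w + 4 > len(final) - 4:
                continue
            code = final[w : w + 4]
            if code in reserved or revcomp(code) in reserved or code == revcomp(code):
                continue
            junctions.append((w, code))
            reserved.add(code)
            reserved.add(revcomp(code))
            placed = True
            break
        if not placed:
            raise DomesticationError(
                f"{part_id}: no collision-free 4-nt junction near position "
                f"{mut.position}"
            )
    junctions.sort()

    patches: list[Patch] = []
    bounds = [0] + [w for w, _ in junctions] + [len(final)]
    for i in range(len(bounds) - 1):
        s = bounds[i]
        e = bounds[i + 1] + (4 if i + 1 < len(bounds) - 1 else 0)
        left_code = None if i == 0 else junctions[i - 1][1]
        right_code = None if i + 1 == len(bounds) - 1 else junctions[i][1]
        muts_here = [m for m in mutations if s <= m.position < e]
        patches.append(Patch((s, e), left_code, right_code, muts_here))

    # primers and reconstructed amplicons
    primers: list[PrimerPair] = []
    amplicons: list[DnaMolecule] = []
    for i, patch in enumerate(patches):
        s, e = patch.span
        first, last = i == 0, i == len(patches) - 1
        fwd_tpl = final[s + (0 if first else 4) :]
        fwd_ext = (
            _terminal_fwd_extension(five_site.code)
            if first
            else BSMBI.recognition + _SPACER + patch.junction_left
        )
        fwd_anneal = _pick_anneal(fwd_tpl)
        rev_tpl = revcomp(final[: e - (0 if last else 4)])
        rev_ext = (
            _terminal_rev_extension(three_site.code)
            if last
            else BSMBI.recognition + _SPACER + revcomp(patch.junction_right)
        )
        rev_anneal = _pick_anneal(rev_tpl)
        primers.append(
            PrimerPair(
                forward=Primer(
                    f"{part_id}.p{i + 1}F", fwd_ext, fwd_anneal,
                    round(MeltingTemp.Tm_NN(fwd_anneal), 1),
                ),
                reverse=Primer(
                    f"{part_id}.p{i + 1}R", rev_ext, rev_anneal,
                    round(MeltingTemp.Tm_NN(rev_anneal), 1),
                ),
            )
        )
        amplicons.append(
            DnaMolecule.linear(
                _amplicon_seq(final, (s, e), first, last, five_site.code, three_site.code),
                name=f"{part_id}.patch{i + 1}",
            )
        )

    if pupd2 is None:
        from .backbones import build_pupd2

        pupd2 = build_pupd2()
    result = one_pot_reaction(amplicons, pupd2, BSMBI)
    entry_clone = result.desired
    assert entry_clone is not None
    entry_clone.name = f"pUPD2:{part_id}"

    part = Part(
        id=part_id,
        insert=DnaMolecule.linear(final, name=part_id),
        five_site=five_site,
        three_site=three_site,
        category=category,
        functional_class=functional_class or category,
        is_cds=is_cds,
        forbidden=tuple(avoid),
    )
    # safety invariants: site-free insert, preserved translation
    assert not scan_internal(part.insert, avoid)
    if is_cds:
        assert translate(final) == translate(raw.seq)

    return DomesticationPlan(
        part_id=part_id,
        patches=patches,
        primers=primers,
        predicted_entry_clone=entry_clone,
        codon_changes=codon_changes,
        part=part,
        mutations=mutations + boundary_mutations,
        amplicons=amplicons,
        short_synthesis=len(raw.seq) < short_threshold,
    )


def primer_sheet(plans: Sequence[DomesticationPlan]) -> list[dict]:
    """Order-sheet rows: primer id, full 5'->3' sequence, length, Tm, purpose."""
    rows = []
    for plan in plans:
        for i, pair in enumerate(plan.primers):
            for p, direction in ((pair.forward, "F"), (pair.reverse, "R")):
                rows.append(
                    {
                        "primer_id": p.name,
                        "sequence_5to3": p.sequence,
                        "length": len(p.sequence),
                        "anneal_tm": p.tm_anneal,
                        "purpose": f"{plan.part_id} patch {i + 1} {direction}",
                    }
                )
    return rows
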