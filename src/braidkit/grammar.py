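"""The default GoldenBraid grammar used by this package.

The grammar is the set of 4-bp fusion-site codes that gives every genetic
element its identity (promoter, CDS, terminator, ...) and forces parts to
assemble in order. The concrete 4-mers are configuration, not biology: any
set that is pairwise distinct, palindrome-free and closed against
reverse-complement collisions works. The defaults below are such a set; they
can be replaced wholesale from a YAML file with :func:`load_grammar`.

Three tiers of codes exist:

* **part grammar** — junctions between parts inside one transcriptional unit
  (promoter|CDS, CDS|terminator, tag and linker junctions);
* **unit grammar** — junctions between transcriptional units at the omega
  level; a unit's pair of codes is conferred by the alpha backbone it was
  assembled in (position codes C0..C4 plus the chain terminator END);
* **entry codes** — the pUPD2 universal cloning ends added by the terminal
  domestication primers.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .seqmodel import GrammarSet, GrammarSite

__all__ = [
    "DEFAULT_GRAMMAR",
    "PART_JUNCTIONS",
    "UNIT_JUNCTIONS",
    "ENTRY_JUNCTIONS",
    "default_grammar",
    "load_grammar",
]

# Part-level junction codes (within a transcriptional unit).
PART_JUNCTIONS: dict[str, str] = {
    "unit5": "GGAG",   # vector arm | promoter
    "prom3": "AATG",   # promoter | CDS (or N-tag); carries the start codon context
    "ntag3": "CCAT",   # N-tag | CDS
    "cds3x": "TTCG",   # CDS | C-tag / barcode (fusion variant)
    "cds3": "GCTT",    # CDS | terminator
    "unit3": "CGCT",   # terminator | vector arm
}

# Unit-level junction codes (between transcriptional units, omega tier).
UNIT_JUNCTIONS: dict[str, str] = {
    "U0": "GTCA",   # omega arm | first unit (C0)
    "U1": "ACTG",
    "U2": "CTGA",
    "U3": "TCCA",
    "U4": "CGGT",
    "UEND": "GCAA",  # last unit | omega arm
    "OMID": "TGGC",  # omega1 | omega2 junction at the next alpha round
}

# pUPD2 universal entry codes (added by the terminal domestication primers).
ENTRY_JUNCTIONS: dict[str, str] = {
    "E5": "CTCG",
    "E3": "CTCA",
}

# Default (five_site, three_site) junction names per part category. The
# planner treats the grammar, not the category label, as authoritative;
# these defaults are what the domesticator and fixture generator mint.
CATEGORY_SITES: dict[str, tuple[str, str]] = {
    "promoter": ("unit5", "prom3"),
    "N-tag": ("prom3", "ntag3"),
    "CDS": ("prom3", "cds3"),
    "C-tag": ("cds3x", "cds3"),
    "linker": ("ntag3", "cds3x"),
    "terminator": ("cds3", "unit3"),
    "barcode": ("cds3x", "cds3"),
    "sgRNA": ("prom3", "cds3"),
    "other": ("prom3", "cds3"),
}

_LABELS = {
    "unit5": "vector|promoter",
    "prom3": "promoter|CDS",
    "ntag3": "N-tag|CDS",
    "cds3x": "CDS|C-tag",
    "cds3": "CDS|terminator",
    "unit3": "terminator|vector",
    "U0": "omega-arm|unit-1",
    "U1": "unit-1|unit-2",
    "U2": "unit-2|unit-3",
    "U3": "unit-3|unit-4",
    "U4": "unit-4|unit-5",
    "UEND": "last-unit|omega-arm",
    "OMID": "omega1|omega2",
    "E5": "pUPD2 arm|insert",
    "E3": "insert|pUPD2 arm",
}


def default_grammar() -> GrammarSet:
    sites = {
        name: GrammarSite(code, _LABELS.get(name, name))
        for name, code in {**PART_JUNCTIONS, **UNIT_JUNCTIONS, **ENTRY_JUNCTIONS}.items()
    }
    return GrammarSet(sites, category_sites=CATEGORY_SITES)


DEFAULT_GRAMMAR = default_grammar()


def load_grammar(path: str | Path) -> GrammarSet:
    """Load a grammar from YAML: ``junctions:`` name->code, ``categories:``
    category->[five_junction, three_junction]."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    junctions = raw.get("junctions", {})
    categories = {
        cat: (pair[0], pair[1]) for cat, pair in (raw.get("categories") or {}).items()
    }
    sites = {
        name: GrammarSite(str(code), _LABELS.get(name, name))
        for name, code in junctions.items()
    }
    return GrammarSet(sites, category_sites=categories or None)
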