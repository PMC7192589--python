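"""Built-in type IIS enzyme definitions and a YAML loader for overrides.

Geometry follows standard catalog values: each enzyme binds its recognition
sequence and cuts downstream, leaving a 4-nt 5' overhang.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .seqmodel import EnzymeSpec

__all__ = ["BSAI", "BSMBI", "BBSI", "STANDARD_ENZYMES", "load_enzymes", "get_enzyme"]

BSAI = EnzymeSpec(name="BsaI", recognition="GGTCTC", spacer_len=1)
BSMBI = EnzymeSpec(name="BsmBI", recognition="CGTCTC", spacer_len=1)
BBSI = EnzymeSpec(name="BbsI", recognition="GAAGAC", spacer_len=2)

STANDARD_ENZYMES: dict[str, EnzymeSpec] = {e.name: e for e in (BSAI, BSMBI, BBSI)}


def load_enzymes(path: str | Path) -> dict[str, EnzymeSpec]:
    """Load enzyme definitions from a YAML mapping.

    Expected form::

        BsaI: {recognition: GGTCTC, spacer_len: 1, overhang_len: 4}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    enzymes = {}
    for name, spec in raw.items():
        enzymes[name] = EnzymeSpec(
            name=name,
            recognition=spec["recognition"],
            spacer_len=int(spec["spacer_len"]),
            overhang_len=int(spec.get("overhang_len", 4)),
        )
    return enzymes


def get_enzyme(name: str, table: dict[str, EnzymeSpec] | None = None) -> EnzymeSpec:
    table = table or STANDARD_ENZYMES
    try:
        return table[name]
    except KeyError:
        raise KeyError(
            f"unknown enzyme {name!r}; known: {sorted(table)}"
        ) from None
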