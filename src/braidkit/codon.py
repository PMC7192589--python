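"""Codon usage table for *Dictyostelium discoideum* and codon helpers.

The bundled table (``data/dicty_codon_usage.csv``) holds approximate
genome-wide synonymous-codon fractions for the strongly AT-biased
*D. discoideum* genome; most amino acids are dominated by an A/T-ending
codon. Absolute fractions are configuration: what the domesticator consumes
is the *ranking* of synonymous codons. Users can supply their own table as a
``{codon: fraction}`` mapping or a CSV with columns codon, amino_acid,
fraction.
"""

from __future__ import annotations

import csv
from functools import lru_cache
from importlib import resources
from pathlib import Path

from Bio.Seq import Seq

__all__ = [
    "CodonTable",
    "load_usage",
    "default_usage",
    "GENETIC_CODE",
    "SYNONYMS",
    "translate",
]

_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
GENETIC_CODE: dict[str, str] = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}

SYNONYMS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in GENETIC_CODE.items():
    SYNONYMS.setdefault(_aa, ())
SYNONYMS = {
    aa: tuple(sorted(c for c, a in GENETIC_CODE.items() if a == aa))
    for aa in set(GENETIC_CODE.values())
}


def translate(seq: str) -> str:
    """Translate a CDS (standard code); trailing partial codon ignored."""
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


class CodonTable:
    """Synonymous codon usage: fraction per codon, ranked per amino acid."""

    def __init__(self, fractions: dict[str, float]) -> None:
        self.fractions = {c.upper().replace("U", "T"): float(f) for c, f in fractions.items()}
        for codon in self.fractions:
            if codon not in GENETIC_CODE:
                raise ValueError(f"not a codon: {codon!r}")

    def fraction(self, codon: str) -> float:
        return self.fractions.get(codon.upper(), 0.0)

    def ranked_synonyms(self, codon_or_aa: str) -> list[str]:
        """Synonymous codons from most to least used (deterministic tie-break)."""
        aa = GENETIC_CODE[codon_or_aa] if len(codon_or_aa) == 3 else codon_or_aa
        return sorted(SYNONYMS[aa], key=lambda c: (-self.fraction(c), c))

    def best_codon(self, aa: str) -> str:
        return self.ranked_synonyms(aa)[0]

    def weights(self, aa: str) -> list[tuple[str, float]]:
        return [(c, self.fraction(c)) for c in SYNONYMS[aa]]


def load_usage(path: str | Path) -> CodonTable:
    with open(path) as fh:
        rows = list(csv.DictReader(fh))
    return CodonTable({row["codon"]: float(row["fraction"]) for row in rows})


@lru_cache(maxsize=1)
def default_usage() -> CodonTable:
    """The bundled *D. discoideum* usage table."""
    ref = resources.files("braidkit.data").joinpath("dicty_codon_usage.csv")
    with resources.as_file(ref) as path:
        return load_usage(path)
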