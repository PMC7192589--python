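"""Shared fixtures: the backbone kit, a seeded synthetic library, and
helpers for minting grammar-chained test parts."""

from __future__ import annotations

import numpy as np
import pytest

from braidkit import DnaMolecule, GrammarSite, Part
from braidkit.backbones import default_kit
from braidkit.enzymes import BBSI, BSAI, BSMBI
from braidkit.fixtures import FixtureSpec, generate_fixtures

ENZYMES = (BSAI, BSMBI, BBSI)

#: Extra 4-mers, disjoint from the default grammar codes and their reverse
#: complements, for chains longer than the stock category junctions allow.
EXTRA_CODES = ["TAGG", "GATA", "TCAC", "ATCC", "GTTG"]

#: A 9-code chain (8 parts) from the alpha arm's GGAG to its CGCT.
CHAIN9 = ["GGAG", "AATG", "CCAT", "TTCG", "TAGG", "GATA", "TCAC", "GCTT", "CGCT"]


def site_free_dna(rng: np.random.Generator, length: int, at: float = 0.6) -> str:
    """Random sequence with no BsaI/BsmBI/BbsI recognition on either strand."""
    from braidkit.backbones import random_dna, scrub_sites

    p = (at / 2, (1 - at) / 2, (1 - at) / 2, at / 2)
    return scrub_sites(random_dna(rng, length, p))


def make_chain_parts(codes: list[str], rng: np.random.Generator,
                     length: int = 120) -> list[Part]:
    """One part per adjacent code pair, with random site-free inserts."""
    parts = []
    for i in range(len(codes) - 1):
        parts.append(
            Part(
                id=f"chain{i}",
                insert=DnaMolecule.linear(site_free_dna(rng, length), name=f"chain{i}"),
                five_site=GrammarSite(codes[i]),
                three_site=GrammarSite(codes[i + 1]),
                category="other",
                forbidden=(BSAI, BSMBI),
            )
        )
    return parts


@pytest.fixture(scope="session")
def kit():
    return default_kit()


@pytest.fixture(scope="session")
def fset():
    return generate_fixtures(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def cats(fset):
    return fset.parts_by_category()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
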