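"""Readers and writers for the standard formats.

GenBank flat files (plasmids and backbones, features preserved), FASTA (raw
parts), the registry CSV (id, category, functional_class, five_site,
three_site, sequence_file) and JSON-style plan/report documents. GenBank and
FASTA go through Biopython's SeqIO; the registry through pandas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .grammar import DEFAULT_GRAMMAR
from .seqmodel import Backbone, DnaMolecule, Feature, GrammarSet, Part

__all__ = [
    "to_seqrecord",
    "from_seqrecord",
    "write_genbank",
    "read_genbank",
    "write_fasta",
    "read_fasta",
    "write_registry",
    "read_registry",
    "write_fixture_files",
    "write_json",
    "read_json",
]

REGISTRY_COLUMNS = [
    "id",
    "category",
    "functional_class",
    "five_site",
    "three_site",
    "is_cds",
    "sequence_file",
]


def to_seqrecord(mol: DnaMolecule) -> SeqRecord:
    rec = SeqRecord(
        Seq(mol.seq),
        id=(mol.name or "molecule")[:40],
        name=(mol.name or "molecule").replace(" ", "_")[:16],
        description=mol.name or "",
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = mol.topology
    for f in mol.annotations:
        rec.features.append(
            SeqFeature(
                FeatureLocation(f.start, f.end, strand=f.strand),
                type="misc_feature",
                qualifiers={"label": [f.label]},
            )
        )
    return rec


def from_seqrecord(rec: SeqRecord) -> DnaMolecule:
    topology = rec.annotations.get("topology", "linear")
    feats = []
    for f in rec.features:
        if f.type != "misc_feature":
            continue
        label = (f.qualifiers.get("label") or [f.type])[0]
        feats.append(
            Feature(label, int(f.location.start), int(f.location.end),
                    f.location.strand or 1)
        )
    name = rec.description or rec.id
    if topology == "circular":
        return DnaMolecule.circular(str(rec.seq), name=name, annotations=feats)
    return DnaMolecule.linear(str(rec.seq), name=name, annotations=feats)


def write_genbank(mols: DnaMolecule | Iterable[DnaMolecule], path: str | Path) -> None:
    if isinstance(mols, DnaMolecule):
        mols = [mols]
    SeqIO.write([to_seqrecord(m) for m in mols], str(path), "genbank")


def read_genbank(path: str | Path) -> list[DnaMolecule]:
    return [from_seqrecord(r) for r in SeqIO.parse(str(path), "genbank")]


def write_fasta(mols: Iterable[DnaMolecule], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(m.seq), id=m.name or f"seq{i}", description="")
        for i, m in enumerate(mols)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[DnaMolecule]:
    return [
        DnaMolecule.linear(str(r.seq), name=r.id) for r in SeqIO.parse(str(path), "fasta")
    ]


def write_registry(
    parts: Sequence[Part], outdir: str | Path, fasta_name: str = "parts.fasta"
) -> Path:
    """Write a part registry: one CSV plus one multi-FASTA of inserts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([p.insert for p in parts], outdir / fasta_name)
    frame = pd.DataFrame(
        [
            {
                "id": p.id,
                "category": p.category,
                "functional_class": p.functional_class,
                "five_site": p.five_site.code,
                "three_site": p.three_site.code,
                "is_cds": p.is_cds,
                "sequence_file": fasta_name,
            }
            for p in parts
        ],
        columns=REGISTRY_COLUMNS,
    )
    csv_path = outdir / "registry.csv"
    frame.to_csv(csv_path, index=False)
    return csv_path


def read_registry(csv_path: str | Path, grammar: GrammarSet | None = None) -> list[Part]:
    """Read a registry CSV back into Part objects (grammar codes included)."""
    from .enzymes import BSAI, BSMBI
    from .seqmodel import GrammarSite

    grammar = grammar or DEFAULT_GRAMMAR
    csv_path = Path(csv_path)
    frame = pd.read_csv(csv_path)
    by_file: dict[str, dict[str, DnaMolecule]] = {}
    parts = []
    code_to_site = {s.code: s for s in grammar.sites.values()}
    for row in frame.to_dict("records"):
        fasta = str(row["sequence_file"])
        if fasta not in by_file:
            by_file[fasta] = {m.name: m for m in read_fasta(csv_path.parent / fasta)}
        insert = by_file[fasta][str(row["id"])]
        five = code_to_site.get(str(row["five_site"]), GrammarSite(str(row["five_site"])))
        three = code_to_site.get(str(row["three_site"]), GrammarSite(str(row["three_site"])))
        parts.append(
            Part(
                id=str(row["id"]),
                insert=insert,
                five_site=five,
                three_site=three,
                category=str(row["category"]),
                functional_class=str(row["functional_class"]),
                is_cds=bool(row["is_cds"]),
                forbidden=(BSAI, BSMBI),
            )
        )
    return parts


def write_fixture_files(fixture_set, outdir: str | Path) -> dict[str, Path]:
    """Emit the full fixture bundle: registry CSV + FASTA, raw-part FASTA,
    GenBank backbones and the ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["registry"] = write_registry(fixture_set.parts, outdir)
    raw_path = outdir / "raw_parts.fasta"
    write_fasta([rp.raw for rp in fixture_set.raw_parts], raw_path)
    paths["raw_parts"] = raw_path
    bb_dir = outdir / "backbones"
    bb_dir.mkdir(exist_ok=True)
    for bb in fixture_set.kit.by_id().values():
        p = bb_dir / f"{bb.id}.gb"
        write_genbank(bb.molecule, p)
        paths[bb.id] = p
    gt_path = outdir / "ground_truth.json"
    write_json(fixture_set.ground_truth(), gt_path)
    paths["ground_truth"] = gt_path
    return paths


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
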