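"""Readers and writers for the pipeline's interchange formats.

Plain-text formats throughout: FASTA for sequences (via Biopython), TSV for
every table, JSON for the run summary.  All coordinates are 0-based
half-open; sequences are uppercase IUPAC.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .qc import CloneRecord, GenotypeTable
from .reference import REQUIRED_COLUMNS, ReferenceDB


class ParseError(ValueError):
    """Malformed input file; message names the file (and line where known)."""


def _fasta_records(path) -> list[SeqRecord]:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # pragma: no cover - biopython raises rarely
        raise ParseError(f"{path}: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_clones_fasta(records: Sequence[CloneRecord], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def write_sample_map(records: Sequence[CloneRecord], path) -> None:
    pd.DataFrame(
        {
            "clone_id": [r.id for r in records],
            "root_system": [r.root_system for r in records],
            "sub_locality": [r.sub_locality for r in records],
            "main_locality": [r.main_locality for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_sample_map(path) -> pd.DataFrame:
    df = read_tsv(path)
    required = {"clone_id", "root_system", "sub_locality", "main_locality"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: sample map lacks columns {sorted(missing)}")
    return df


def read_clones(fasta_path, sample_map_path) -> list[CloneRecord]:
    """Clone FASTA + sample map -> clone records; unmapped clones are an error."""
    seqs = _fasta_records(fasta_path)
    smap = read_sample_map(sample_map_path).set_index("clone_id")
    orphans = [r.id for r in seqs if r.id not in smap.index]
    if orphans:
        raise ParseError(
            f"{fasta_path}: clones absent from sample map: {orphans[:5]}"
            + ("..." if len(orphans) > 5 else "")
        )
    records = []
    for r in seqs:
        row = smap.loc[r.id]
        records.append(
            CloneRecord(
                id=r.id,
                sequence=str(r.seq).upper(),
                root_system=row["root_system"],
                sub_locality=row["sub_locality"],
                main_locality=row["main_locality"],
            )
        )
    return records


def write_reference_fasta(ref: ReferenceDB, path) -> None:
    """Header carries region bounds and taxonomy:
    ``>ref_id regions=<its1_end>:<5.8s_end> taxonomy=<species>|<genus>|<family>``
    """
    recs = []
    for _, row in ref.table.iterrows():
        desc = (
            f"regions={row['its1_end']}:{row['fivep8s_end']} "
            f"taxonomy={row['species']}|{row['genus']}|{row['family']}"
        )
        recs.append(SeqRecord(Seq(row["sequence"]), id=row["ref_id"], description=desc))
    SeqIO.write(recs, str(path), "fasta")


def read_reference_fasta(path) -> ReferenceDB:
    rows = []
    for i, rec in enumerate(_fasta_records(path), start=1):
        fields = dict(
            part.split("=", 1) for part in rec.description.split()[1:] if "=" in part
        )
        if "regions" not in fields or "taxonomy" not in fields:
            raise ParseError(
                f"{path}: record {i} ({rec.id}): header must carry "
                "'regions=a:b taxonomy=species|genus|family'"
            )
        try:
            a, b = (int(x) for x in fields["regions"].split(":"))
            species, genus, family = fields["taxonomy"].split("|")
        except ValueError as exc:
            raise ParseError(f"{path}: record {i} ({rec.id}): {exc}") from exc
        rows.append(
            {
                "ref_id": rec.id,
                "sequence": str(rec.seq).upper(),
                "species": species,
                "genus": genus,
                "family": family,
                "its1_end": a,
                "fivep8s_end": b,
            }
        )
    return ReferenceDB(pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)))


def write_genotypes(genotypes: GenotypeTable, fasta_path, table_path) -> None:
    SeqIO.write(
        (
            SeqRecord(Seq(row["sequence"]), id=row["genotype_id"], description="")
            for _, row in genotypes.table.iterrows()
        ),
        str(fasta_path),
        "fasta",
    )
    table = genotypes.table.drop(columns=["sequence"]).join(
        genotypes.counts.reset_index(drop=True)
    )
    table.insert(1, "sequence", genotypes.table["sequence"])
    table["member_clones"] = [
        ",".join(genotypes.members[g]) for g in genotypes.table["genotype_id"]
    ]
    table.to_csv(table_path, sep="\t", index=False)


def read_genotypes(table_path) -> GenotypeTable:
    df = read_tsv(table_path)
    meta_cols = ["genotype_id", "sequence", "n_clones", "n_root_systems"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ParseError(f"{table_path}: genotype table lacks columns {missing}")
    rs_cols = [c for c in df.columns if c not in meta_cols + ["member_clones"]]
    counts = df[rs_cols].astype(int)
    counts.index = df["genotype_id"]
    members = {
        row["genotype_id"]: str(row.get("member_clones", "")).split(",")
        for _, row in df.iterrows()
    }
    return GenotypeTable(df[meta_cols].copy(), counts, members)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        return pd.read_csv(path, sep="\t", index_col=index_col)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_incidence(incidence: pd.DataFrame, path) -> None:
    out = incidence.copy()
    out.index.name = "otu_id"
    out.to_csv(path, sep="\t")


def read_incidence(path) -> pd.DataFrame:
    return read_tsv(path, index_col=0)


def write_summary(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, default=str) + "\n")


def read_summary(path) -> dict:
    return json.loads(Path(path).read_text())
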