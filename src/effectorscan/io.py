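"""Readers and writers for every external table and sequence format.

One fixed dialect per format: expression TSVs carry genes in rows (gene-id
column ``gene_id``) and samples in columns, with a companion metadata TSV
mapping each sample to tissue / stage / sex / replicate; protein sequences are
plain FASTA; peptide evidence, annotation and domain counts are headered
TSVs; assay records are headered CSVs.  All writes round-trip losslessly
through the corresponding reader.
"""
from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ecology import ChoiceAssayRecord, DissectionRecord, ParasitismAssayRecord
from .effectors import ProteinRecord
from .errors import InputError
from .expansion import DomainCountTable
from .profiles import ExpressionMatrix

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_fasta",
    "write_fasta",
    "read_peptide_table",
    "write_peptide_table",
    "read_annotation_table",
    "write_annotation_table",
    "read_domain_count_table",
    "write_domain_count_table",
    "read_parasitism_records",
    "write_parasitism_records",
    "read_choice_records",
    "write_choice_records",
    "read_dissection_records",
    "write_dissection_records",
    "file_checksum",
]


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required column(s) {missing}")


def read_expression_table(
    path: str | Path, metadata_path: str | Path
) -> ExpressionMatrix:
    """TPM matrix TSV (gene_id + sample columns) plus sample-metadata TSV."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id":
        raise InputError(f"{path}: first column must be 'gene_id'; got {df.columns[0]!r}")
    df = df.set_index("gene_id")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad][0]
            raise InputError(
                f"{path}: non-numeric TPM value {df.loc[gene, col]!r} "
                f"at gene {gene!r}, sample {col!r}"
            )
        neg = numeric < 0
        if neg.any():
            gene = df.index[neg][0]
            raise InputError(
                f"{path}: negative TPM value {numeric[neg].iloc[0]} "
                f"at gene {gene!r}, sample {col!r}"
            )
        df[col] = numeric
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    _require_columns(meta, ["sample_id", "tissue", "stage", "sex", "replicate"], metadata_path)
    meta = meta.set_index("sample_id")
    return ExpressionMatrix(df, meta)


def write_expression_table(
    matrix: ExpressionMatrix, path: str | Path, metadata_path: str | Path
) -> None:
    # full repr precision so write -> read is lossless
    matrix.values.rename_axis("gene_id").to_csv(path, sep="\t")
    matrix.metadata.rename_axis("sample_id").to_csv(metadata_path, sep="\t")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Protein FASTA; identifiers must be unique, sequences are uppercased."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise InputError(f"{path}: duplicate identifier {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, str(rec.seq)))
    return records


def write_fasta(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(p.sequence), id=p.identifier, description="") for p in proteins),
        str(path),
        "fasta",
    )


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str})
    _require_columns(df, ["peptide", "spectrum_count"], path)
    if df["peptide"].isna().any() or (df["peptide"].str.len() == 0).any():
        raise InputError(f"{path}: empty peptide sequence")
    df["peptide"] = df["peptide"].str.upper()
    return df


def write_peptide_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    _require_columns(df, ["gene_id", "domain_accessions", "function_text"], path)
    if df["gene_id"].duplicated().any():
        dupes = df["gene_id"][df["gene_id"].duplicated()].unique()
        raise InputError(f"{path}: duplicate gene_id(s) {list(dupes)}")
    return df


def write_annotation_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_domain_count_table(path: str | Path) -> DomainCountTable:
    """Long-format TSV (species, domain, count) -> species × domain table."""
    df = pd.read_csv(path, sep="\t", dtype={"species": str, "domain": str})
    _require_columns(df, ["species", "domain", "count"], path)
    if df.duplicated(subset=["species", "domain"]).any():
        raise InputError(f"{path}: duplicate (species, domain) rows")
    wide = (
        df.pivot(index="species", columns="domain", values="count")
        .fillna(0)
        .sort_index()
    )
    wide = wide[sorted(wide.columns)]
    return DomainCountTable(wide)


def write_domain_count_table(table: DomainCountTable, path: str | Path) -> None:
    long = (
        table.counts.rename_axis("species")
        .reset_index()
        .melt(id_vars="species", var_name="domain", value_name="count")
        .sort_values(["species", "domain"], kind="mergesort")
    )
    long.to_csv(path, sep="\t", index=False)


_PARASITISM_COLUMNS = [
    "replicate",
    "host_species",
    "host_age_days",
    "mode",
    "n_hosts",
    "n_emerged_host_adults",
    "n_emerged_wasps",
]


def read_parasitism_records(path: str | Path) -> list[ParasitismAssayRecord]:
    df = pd.read_csv(path)
    _require_columns(df, _PARASITISM_COLUMNS, path)
    return [
        ParasitismAssayRecord(
            replicate=str(r.replicate),
            host_species=str(r.host_species),
            host_age_days=int(r.host_age_days),
            mode=str(r.mode),
            n_hosts=int(r.n_hosts),
            n_emerged_host_adults=int(r.n_emerged_host_adults),
            n_emerged_wasps=int(r.n_emerged_wasps),
        )
        for r in df.itertuples(index=False)
    ]


def write_parasitism_records(
    records: Iterable[ParasitismAssayRecord], path: str | Path
) -> None:
    pd.DataFrame([vars(r) for r in records], columns=_PARASITISM_COLUMNS).to_csv(
        path, index=False
    )


_CHOICE_COLUMNS = ["replicate", "age_x", "n1", "nx", "duration_h"]


def read_choice_records(path: str | Path) -> list[ChoiceAssayRecord]:
    df = pd.read_csv(path)
    _require_columns(df, _CHOICE_COLUMNS, path)
    return [
        ChoiceAssayRecord(
            replicate=str(r.replicate),
            age_x=int(r.age_x),
            n1=int(r.n1),
            nx=int(r.nx),
            duration_h=float(r.duration_h),
        )
        for r in df.itertuples(index=False)
    ]


def write_choice_records(records: Iterable[ChoiceAssayRecord], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in records], columns=_CHOICE_COLUMNS).to_csv(
        path, index=False
    )


_DISSECTION_COLUMNS = ["replicate", "group", "n_dissected", "n_with_eggs"]


def read_dissection_records(path: str | Path) -> list[DissectionRecord]:
    df = pd.read_csv(path)
    _require_columns(df, _DISSECTION_COLUMNS, path)
    return [
        DissectionRecord(
            replicate=str(r.replicate),
            group=str(r.group),
            n_dissected=int(r.n_dissected),
            n_with_eggs=int(r.n_with_eggs),
        )
        for r in df.itertuples(index=False)
    ]


def write_dissection_records(
    records: Iterable[DissectionRecord], path: str | Path
) -> None:
    pd.DataFrame([vars(r) for r in records], columns=_DISSECTION_COLUMNS).to_csv(
        path, index=False
    )
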