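"""Readers and writers for the pipeline's on-disk formats.

All tables are plain TSV with a leading comment line naming the schema
version (``# acetylstoich schema=1 table=<name>``); readers skip comment
lines. FASTA goes through Biopython; the accession is the first
whitespace-delimited token of the header.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .quantify import SITE_TABLE_COLUMNS
from .simulate import QUANT_COLUMNS, StudyConfig

SCHEMA_VERSION = 1

__all__ = [
    "SchemaError",
    "read_fasta",
    "write_fasta",
    "read_table",
    "write_table",
    "read_quant_table",
    "read_annotations",
    "write_json",
    "read_config",
    "write_config",
]


class SchemaError(ValueError):
    """An input file does not match the expected schema."""


def read_fasta(path) -> dict[str, str]:
    """Protein sequences keyed by accession (first header token)."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        sequences[record.id] = str(record.seq)
    if not sequences:
        raise SchemaError(f"no FASTA records in {path}")
    return sequences


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=protein_id, description="")
        for protein_id, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def write_table(df: pd.DataFrame, path, table: str) -> None:
    """TSV with a schema-version comment header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# acetylstoich schema={SCHEMA_VERSION} table={table}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path, required: Sequence[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty table") from exc
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def read_quant_table(path) -> pd.DataFrame:
    """Fragment-level quant table with per-line diagnostics on bad rows."""
    df = read_table(path, required=QUANT_COLUMNS)
    problems = []
    for col in ("light_area", "heavy_area"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | (values < 0)
        for idx in df.index[bad][:10]:
            problems.append(f"line {idx + 3}: {col} must be a non-negative number")
        df[col] = values
    if problems:
        raise SchemaError("; ".join(problems))
    return df


def read_site_table(path) -> pd.DataFrame:
    return read_table(path, required=SITE_TABLE_COLUMNS)


def read_annotations(path, names_path=None):
    """Long-format (category_id, protein_id) TSV plus optional name map."""
    df = read_table(path, required=["category_id", "protein_id"])
    names = None
    if names_path is not None:
        names_df = read_table(names_path, required=["category_id", "category_name"])
        names = dict(zip(names_df["category_id"], names_df["category_name"]))
    return df, names


def write_json(obj, path) -> None:
    payload = {"schema": SCHEMA_VERSION, **obj}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_config(path) -> StudyConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(StudyConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    for key in ("length_range", "groups", "charges", "length_bounds",
                "category_size_range", "baseline_range"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    cfg = StudyConfig(**raw)
    cfg.validate()
    return cfg


def write_config(cfg: StudyConfig, path) -> None:
    """Echo the effective configuration verbatim next to the outputs."""
    data = cfg.to_dict()
    for key, value in data.items():
        if isinstance(value, tuple):
            data[key] = list(value)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
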