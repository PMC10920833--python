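"""Readers and writers for the standard formats used by the pipeline."""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .align import DistanceMatrix, Msa, SequenceRecord
from .errors import InputError


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records = [
        SequenceRecord(id=r.id, sequence=str(r.seq).upper(), description=r.description)
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise InputError(f"no sequences found in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise InputError(f"duplicate sequence ids in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 60) -> None:
    bio = [
        _BioRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def write_msa_fasta(msa: Msa, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(msa.ids, msa.rows):
            fh.write(f">{name}\n{row}\n")


def read_msa(path: str | Path, fmt: str = "fasta") -> Msa:
    """Read an aligned FASTA or Stockholm file into an :class:`Msa`."""
    alignment = AlignIO.read(str(path), fmt)
    return Msa(
        ids=[r.id for r in alignment],
        rows=[str(r.seq).upper().replace(".", "-") for r in alignment],
    )


def write_matrix_tsv(
    ids: list[str], values: np.ndarray, path: str | Path, float_format: str | None = None
) -> None:
    frame = pd.DataFrame(np.asarray(values), index=ids, columns=ids)
    frame.to_csv(path, sep="\t", index_label="id", float_format=float_format)


def read_matrix_tsv(path: str | Path) -> tuple[list[str], np.ndarray]:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if list(frame.index) != list(frame.columns):
        raise InputError(f"matrix in {path} has mismatched row/column ids")
    return [str(i) for i in frame.index], frame.to_numpy(dtype=float)


def read_distance_tsv(path: str | Path, d_max: float = 300.0) -> DistanceMatrix:
    ids, values = read_matrix_tsv(path)
    return DistanceMatrix(ids, values, d_max)


def read_glycan_tsv(path: str | Path) -> pd.DataFrame:
    """Glycan input TSV: columns id, iupac_string, optional family_label."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "id" not in frame.columns or "iupac_string" not in frame.columns:
        raise InputError(f"{path} must have columns 'id' and 'iupac_string'")
    if frame["id"].duplicated().any():
        raise InputError(f"duplicate glycan ids in {path}")
    return frame


def write_tsv(rows: list[dict], path: str | Path, columns: list[str]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t")
        writer.writeheader()
        for row in rows:
            writer.writerow(row)
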