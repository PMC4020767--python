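"""File format helpers: FASTA, BED6, TSV."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .clip import READ_COLUMNS
from .seedscan import MatureMiRNA, UtrRecord


def read_utr_fasta(path: str | Path) -> list[UtrRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"UTR FASTA not found: {path}")
    return [
        UtrRecord(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_mirna_fasta(path: str | Path) -> list[MatureMiRNA]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"miRNA FASTA not found: {path}")
    return [
        MatureMiRNA(rec.id, str(rec.seq).upper().replace("T", "U"))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seq_records, str(path), "fasta")


def read_bed6(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"BED file not found: {path}")
    df = pd.read_csv(path, sep="\t", header=None, names=READ_COLUMNS)
    return df


def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    df[READ_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"TSV file not found: {path}")
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
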