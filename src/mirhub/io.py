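"""File input/output: FASTA, TSV matrices, gene sets, and checksums.

Conventions
-----------
* FASTA is read/written with Biopython; sequences are canonicalized to the
  DNA T-alphabet on read (RNA input is accepted).
* Matrices are TSV with a header row; the first column is the feature ID.
* Gene sets are two-column TSV (``gene_id``, ``direction``).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seq import canonicalize


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    Sequences are canonicalized (uppercase, U -> T). Duplicate IDs raise.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = canonicalize(str(rec.seq))
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path, *, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a features-by-samples TSV matrix (first column = feature ID)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids in {path}: {dupes[:5]}")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, *, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sample, group) into a mapping."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"group table {path} needs two columns (sample, group)")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def read_library_sizes(path: str | Path) -> pd.Series:
    """Read a two-column TSV (sample, uniquely mapped reads)."""
    df = pd.read_csv(path, sep="\t")
    sizes = pd.Series(df.iloc[:, 1].to_numpy(float), index=df.iloc[:, 0].astype(str))
    if (sizes <= 0).any():
        raise ValueError(f"non-positive library sizes in {path}")
    return sizes


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
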