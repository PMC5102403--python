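"""File I/O for the pipeline's text formats.

TSV dialect: UTF-8, tab-separated, no quoting, a single ``#``-prefixed
header line declaring the column schema. Gene sets use GMT
(name <tab> description <tab> member...), sequences FASTA via Bio.SeqIO.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_gmt",
    "read_gmt",
    "write_fasta",
    "read_fasta",
    "write_json",
    "read_json",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame with a '#'-prefixed header line."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, lineterminator="\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise FormatError(f"{path}: missing '#'-prefixed header line")
        names = header.lstrip("#").rstrip("\n").split("\t")
        df = pd.read_csv(fh, sep="\t", names=names, header=None)
    return df


def write_gmt(gene_sets: dict[str, set[str] | list[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name in sorted(gene_sets):
            members = sorted(gene_sets[name])
            fh.write("\t".join([name, name] + members) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            sets[fields[0]] = set(fields[2:])
    return sets


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_json(obj, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def _jsonify(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
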