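"""Sequence and tree readers plus tabular/jplace writers shared by the CLI.

FASTA/FASTQ parsing goes through Biopython's SeqIO with gzip and format
auto-detection; Newick parsing goes through dendropy behind
:meth:`lshplace.placement.Phylogeny.from_newick`.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterator

from .encoding import EncodingParams
from .index import QueryParams
from .placement import Phylogeny

__all__ = ["read_fastx", "read_newick", "write_fasta", "RunConfig"]


def _open_maybe_gzip(path: str):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastx(path: str) -> Iterator[tuple]:
    """Stream records from a FASTA or FASTQ file (optionally gzipped).

    Yields ``(id, sequence)`` for FASTA and ``(id, sequence, quality)`` for
    FASTQ; sequences are uppercased and ids are the first
    whitespace-delimited token. Raises on malformed or truncated input.
    """
    from Bio import SeqIO

    handle = _open_maybe_gzip(path)
    try:
        first = handle.read(1)
        if not first:
            raise ValueError(f"{path}: empty file")
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        else:
            raise ValueError(f"{path}: not FASTA/FASTQ (starts with {first!r})")
        handle.seek(0)
        for rec in SeqIO.parse(handle, fmt):
            seq = str(rec.seq).upper()
            if fmt == "fastq":
                qual = rec.letter_annotations.get("phred_quality")
                yield rec.id, seq, qual
            else:
                yield rec.id, seq
    finally:
        handle.close()


def read_newick(path: str, rooted_required: bool = True) -> Phylogeny:
    """Parse a rooted Newick tree with stable preorder edge numbering."""
    return Phylogeny.from_newick(path, rooted_required=rooted_required)


def write_fasta(records: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


@dataclass
class RunConfig:
    """The exact configuration of a run, echoed as JSON next to outputs so
    every result is reproducible; index-time parameters are authoritative
    at query time."""

    params: EncodingParams
    qparams: QueryParams
    inputs: dict
    seed: int = 1

    def to_json(self) -> str:
        return json.dumps({
            "params": self.params.to_dict(),
            "qparams": self.qparams.to_dict(),
            "inputs": self.inputs,
            "seed": self.seed,
        }, indent=1)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())
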