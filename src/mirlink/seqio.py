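"""Thin FASTA / GMT I/O wrappers.

FASTA goes through Bio.SeqIO; GMT (tab-separated gene sets: name,
description, member ids) is simple enough to read and write directly.
"""

from __future__ import annotations

import io
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` preserving order."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    ids = [r[0] for r in records]
    if len(ids) != len(set(ids)):
        raise FormatError(f"duplicate sequence ids in {path}")
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


def fasta_bytes(records: list[tuple[str, str]]) -> bytes:
    """Serialize records to FASTA bytes (used for determinism checks)."""
    buf = io.StringIO()
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqs, buf, "fasta")
    return buf.getvalue().encode()


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file into ``{pathway_name: {gene, ...}}``."""
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line with fewer than 3 fields: {line!r}")
            name, _desc, genes = parts[0], parts[1], parts[2:]
            if name in pathways:
                raise FormatError(f"duplicate pathway name {name!r}")
            pathways[name] = set(g for g in genes if g)
    return pathways


def write_gmt(
    pathways: dict[str, set[str]],
    path: str | Path,
    descriptions: dict[str, str] | None = None,
) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name in sorted(pathways):
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc] + sorted(pathways[name])) + "\n")
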