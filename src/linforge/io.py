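"""FASTA input helpers."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO


def read_fasta(path: str | Path) -> list[str]:
    """Contig sequences of a (possibly multi-record) FASTA file, uppercased."""
    seqs = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return seqs


def write_fasta(records: dict[str, str], path: str | Path, width: int = 70) -> None:
    """Write sequences as wrapped multi-FASTA (plain text, deterministic)."""
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
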