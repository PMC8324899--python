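"""Format plumbing: gzip-transparent FASTA/FASTQ reading, simple writers.

Identifiers are taken verbatim up to the first whitespace. All coordinates
written by the pipeline are 0-based half-open.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into a list of (id, uppercase sequence)."""
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Iterate (id, uppercase sequence) over a FASTQ file (gzip transparent)."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq).upper()


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str]]) -> None:
    """Write (id, sequence, quality) triples as Sanger/Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
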