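"""Direct-repeat-anchored CRISPR spacer mining from raw reads.

Spacers are taken as the sequence between two complete, exact
occurrences of the direct-repeat (DR) consensus on the same strand of a
read, filtered to 20-60 nt. Reads are scanned with the DR in both
orientations; spacers observed on the reverse-complement strand are
canonicalized into DR-forward orientation so that clustering merges
observations from either strand. 'N' bases never match the DR (matching
is strictly exact) but are allowed inside spacers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .sequtils import revcomp, validate_dna

MIN_SPACER_LEN = 20
MAX_SPACER_LEN = 60


@dataclass(frozen=True)
class DirectRepeat:
    sequence: str
    label: str = "DR"

    def __post_init__(self) -> None:
        validate_dna(self.sequence, "direct repeat")
        if not 18 <= len(self.sequence) <= 60:
            raise ValueError(
                f"direct repeat length {len(self.sequence)} outside [18, 60]"
            )


@dataclass
class SpacerRecord:
    sequence: str  # canonical DR-forward orientation
    read_id: str
    sample_id: str
    dr_label: str
    dr_orientation: str  # '+' or '-'

    @property
    def length(self) -> int:
        return len(self.sequence)


def find_dr_occurrences(
    read_sequence: str, dr: DirectRepeat | str
) -> list[tuple[int, int, str]]:
    """All exact, complete DR occurrences in a read, both orientations.

    Returns 0-based half-open (start, end, strand) sorted by start;
    overlapping occurrences are all reported. A palindromic DR is
    reported once per position, on the forward strand.
    """
    seq = dr.sequence if isinstance(dr, DirectRepeat) else dr
    hits: list[tuple[int, int, str]] = []
    rc = revcomp(seq)
    for pattern, strand in ((seq, "+"), (rc, "-")):
        if strand == "-" and rc == seq:
            break
        pos = read_sequence.find(pattern)
        while pos != -1:
            hits.append((pos, pos + len(pattern), strand))
            pos = read_sequence.find(pattern, pos + 1)
    hits.sort(key=lambda h: (h[0], h[2]))
    return hits


def spacers_in_read(
    read_sequence: str,
    dr: DirectRepeat | str,
    min_len: int = MIN_SPACER_LEN,
    max_len: int = MAX_SPACER_LEN,
    allow_partial: bool = False,
) -> list[tuple[str, str]]:
    """Canonical (spacer, strand) pairs mined from one read.

    Only the strand with more DR hits is used (ties go to the forward
    strand: a read spanning a strand switch is an artifact, arrays are
    single-stranded per locus). Each gap between consecutive same-strand
    DR copies yields one spacer; read-terminal fragments bounded by a
    single DR are discarded unless ``allow_partial``, as are spacers
    outside [min_len, max_len].
    """
    hits = find_dr_occurrences(read_sequence, dr)
    if not hits or (len(hits) < 2 and not allow_partial):
        return []
    fwd = [h for h in hits if h[2] == "+"]
    rev = [h for h in hits if h[2] == "-"]
    strand_hits, strand = (fwd, "+") if len(fwd) >= len(rev) else (rev, "-")
    if not strand_hits:
        return []
    segments = []
    for (s1, e1, _), (s2, _, _) in zip(strand_hits, strand_hits[1:]):
        if s2 < e1:  # overlapping DR copies leave no spacer
            continue
        segments.append(read_sequence[e1:s2])
    if allow_partial:
        segments.append(read_sequence[: strand_hits[0][0]])
        segments.append(read_sequence[strand_hits[-1][1] :])
    out = []
    for spacer in segments:
        if not min_len <= len(spacer) <= max_len:
            continue
        out.append((spacer if strand == "+" else revcomp(spacer), strand))
    return out


def extract_spacers(
    reads: Iterable[tuple[str, str]],
    dr: DirectRepeat | str,
    sample_id: str = "",
    min_len: int = MIN_SPACER_LEN,
    max_len: int = MAX_SPACER_LEN,
    allow_partial: bool = False,
) -> Iterator[SpacerRecord]:
    """Mine SpacerRecords from an iterable of (read_id, sequence)."""
    dr = dr if isinstance(dr, DirectRepeat) else DirectRepeat(dr)
    for read_id, seq in reads:
        for spacer, strand in spacers_in_read(seq, dr, min_len, max_len, allow_partial):
            yield SpacerRecord(spacer, read_id, sample_id, dr.label, strand)
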