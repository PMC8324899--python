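"""Greedy identity clustering of spacer occurrences (Cd-hit semantics).

Unique sequences are sorted length-descending (ties lexicographic) and
each joins the first existing cluster whose representative it matches at
the identity threshold, else founds a new cluster. The sort makes the
result independent of input record order, and guarantees the
representative is the longest member (ties: lexicographically
smallest). Identity is computed on an end-gap-free semi-global
alignment, with the shorter sequence as denominator — Cd-hit's
convention — so an exact prefix counts as identity 1.0.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import edlib

from .extraction import SpacerRecord

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def pairwise_identity(a: str, b: str) -> float:
    """Matches in the best end-gap-free alignment / length of the shorter.

    The shorter sequence must align end to end; overhangs of the longer
    sequence are free. Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    res = edlib.align(query, target, mode="HW", task="path")
    matches = sum(
        int(n) for n, op in _CIGAR_RE.findall(res["cigar"] or "") if op == "="
    )
    return matches / len(query)


@dataclass
class SpacerCluster:
    cluster_id: str
    representative: str
    member_count_per_sample: Counter = field(default_factory=Counter)
    members: set = field(default_factory=set)  # distinct member sequences

    @property
    def distinct_members(self) -> int:
        return len(self.members)

    @property
    def total_count(self) -> int:
        return sum(self.member_count_per_sample.values())

    @property
    def is_singleton(self) -> bool:
        return self.total_count == 1


def cluster_spacers(
    records: Iterable[SpacerRecord], threshold: float = 0.99
) -> list[SpacerCluster]:
    """Greedy incremental clustering of spacer occurrences at *threshold*."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    counts: dict[str, Counter] = {}
    for rec in records:
        counts.setdefault(rec.sequence, Counter())[rec.sample_id] += 1
    clusters: list[SpacerCluster] = []
    for seq in sorted(counts, key=lambda s: (-len(s), s)):
        home = None
        for cl in clusters:
            if pairwise_identity(seq, cl.representative) >= threshold:
                home = cl
                break
        if home is None:
            home = SpacerCluster(f"cl_{len(clusters) + 1:05d}", seq)
            clusters.append(home)
        home.members.add(seq)
        home.member_count_per_sample.update(counts[seq])
    return clusters


def cluster_overlap(
    clusters_a: list[SpacerCluster],
    clusters_b: list[SpacerCluster],
    threshold: float = 0.99,
) -> tuple[int, int, int]:
    """Venn partition of two cluster sets: (shared, only_a, only_b).

    A pair is shared when the representatives reach the identity
    threshold; pairing is greedy best-first by identity so each cluster
    participates in at most one shared pair.
    """
    pairs = []
    for i, ca in enumerate(clusters_a):
        for j, cb in enumerate(clusters_b):
            ident = pairwise_identity(ca.representative, cb.representative)
            if ident >= threshold:
                pairs.append((ident, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    shared = 0
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        shared += 1
    return shared, len(clusters_a) - shared, len(clusters_b) - shared
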