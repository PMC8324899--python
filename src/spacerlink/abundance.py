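"""Read assignment, coverage normalization, host-virus ratios, dynamics.

The read assigner is a purpose-built best-hit mapper, not a full
aligner: reads are anchored by exact 15-mer probes against an index of
the references and evaluated ungapped at each candidate offset (the
substitution-dominated regime the 2% mismatch post-filter concerns).
Assignments exceeding the mismatch fraction are discarded; ties on the
best score go to the first reference in input order (configurable).

Coverage is mapped bases per reference base (depth). Cross-sample
normalization rescales each sample by total sequenced bp to the sample
with the lowest total, so within-sample ratios (host-virus ratio in
particular) are scale-invariant.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .clustering import SpacerCluster
from .matching import ProtospacerMatch
from .sequtils import encode, revcomp_encoded


@dataclass
class SampleProfile:
    sample_id: str
    total_bp: int
    mapped_bp: dict[str, int]
    ref_lengths: dict[str, int]
    normalized_coverage: dict[str, float] = field(default_factory=dict)

    @property
    def raw_coverage(self) -> dict[str, float]:
        return {r: self.mapped_bp[r] / self.ref_lengths[r] for r in self.ref_lengths}


class ReferenceIndex:
    """Exact k-mer index over a set of reference sequences."""

    def __init__(self, references: list[tuple[str, str]], word_size: int = 15):
        self.word_size = word_size
        self.ids = [r[0] for r in references]
        self.arrays = [encode(seq) for _, seq in references]
        self.lengths = {rid: len(seq) for rid, seq in references}
        self.index: dict[str, list[tuple[int, int]]] = {}
        for ri, (_, seq) in enumerate(references):
            for p in range(0, len(seq) - word_size + 1):
                self.index.setdefault(seq[p : p + word_size], []).append((ri, p))


def _evaluate(read_arr: np.ndarray, ref_arr: np.ndarray, offset: int, min_anchor: int):
    """Ungapped comparison of a read at a candidate offset; allows end clipping.

    Returns (aligned_len, mismatches) or None when the overlap is shorter
    than min_anchor.
    """
    L = len(read_arr)
    r_lo = max(0, -offset)
    r_hi = min(L, len(ref_arr) - offset)
    if r_hi - r_lo < min_anchor:
        return None
    window = ref_arr[offset + r_lo : offset + r_hi]
    mism = int(np.count_nonzero(window != read_arr[r_lo:r_hi]))
    return r_hi - r_lo, mism


def assign_reads(
    reads: Iterable[tuple[str, str]],
    references: list[tuple[str, str]] | ReferenceIndex,
    max_mismatch_frac: float = 0.02,
    word_size: int = 15,
    n_probes: int = 3,
    min_anchor: int = 30,
    multi: str = "first",
) -> dict[str, int]:
    """Best-hit read assignment; returns per-reference mapped bp.

    Each read (both orientations) is probed at ``n_probes`` evenly spaced
    exact words; every candidate (reference, offset) is scored ungapped.
    The location with the most aligned bases (ties: fewest mismatches,
    then first reference in input order) wins; it is kept only when
    mismatches <= max_mismatch_frac * aligned length. ``multi`` controls
    equal-best ties across references: 'first', 'discard' or 'fractional'.
    """
    if multi not in ("first", "discard", "fractional"):
        raise ValueError("multi must be 'first', 'discard' or 'fractional'")
    idx = (
        references
        if isinstance(references, ReferenceIndex)
        else ReferenceIndex(references, word_size)
    )
    w = idx.word_size
    mapped = {rid: 0.0 for rid in idx.ids}
    for _read_id, seq in reads:
        L = len(seq)
        if L < w:
            continue
        probe_positions = sorted({int(p) for p in np.linspace(0, L - w, n_probes)})
        best = None  # (aligned, -mism, candidates)
        for orient in (0, 1):
            s = seq if orient == 0 else None
            arr = encode(seq) if orient == 0 else revcomp_encoded(encode(seq))
            if orient == 1:
                s = arr.tobytes().decode("ascii")
            candidates = set()
            for p in probe_positions:
                for ri, pos in idx.index.get(s[p : p + w], ()):
                    candidates.add((ri, pos - p))
            for ri, offset in candidates:
                ev = _evaluate(arr, idx.arrays[ri], offset, min_anchor)
                if ev is None:
                    continue
                aligned, mism = ev
                key = (aligned, -mism)
                if best is None or key > best[0]:
                    best = (key, [(ri, aligned, mism)])
                elif key == best[0]:
                    best[1].append((ri, aligned, mism))
        if best is None:
            continue
        (aligned, neg_mism), cands = best
        if -neg_mism > max_mismatch_frac * aligned:
            continue
        refs = sorted({ri for ri, _, _ in cands})
        if len(refs) > 1 and multi == "discard":
            continue
        if len(refs) > 1 and multi == "fractional":
            for ri in refs:
                mapped[idx.ids[ri]] += aligned / len(refs)
        else:
            mapped[idx.ids[refs[0]]] += aligned
    return {rid: int(round(v)) for rid, v in mapped.items()}


def profile_sample(
    sample_id: str,
    reads: list[tuple[str, str]],
    references: list[tuple[str, str]] | ReferenceIndex,
    max_mismatch_frac: float = 0.02,
    **kwargs,
) -> SampleProfile:
    idx = (
        references
        if isinstance(references, ReferenceIndex)
        else ReferenceIndex(references)
    )
    total_bp = sum(len(seq) for _, seq in reads)
    mapped = assign_reads(reads, idx, max_mismatch_frac, **kwargs)
    return SampleProfile(sample_id, total_bp, mapped, dict(idx.lengths))


def normalize_coverage(profiles: list[SampleProfile]) -> list[SampleProfile]:
    """Scale every sample's coverage by min(total bp) / total bp (in place)."""
    if not profiles:
        raise ValueError("at least one profile required")
    for p in profiles:
        if p.total_bp <= 0:
            raise ValueError(f"sample {p.sample_id} has zero total bp")
    min_total = min(p.total_bp for p in profiles)
    for p in profiles:
        factor = min_total / p.total_bp
        p.normalized_coverage = {r: c * factor for r, c in p.raw_coverage.items()}
    return profiles


def host_virus_ratio(
    profile: SampleProfile, host_id: str, virus_id: str
) -> float | None:
    """Host normalized coverage over virus normalized coverage.

    Returns None (a distinct 'undefined' sentinel, never +inf) when the
    virus has zero coverage.
    """
    cov = profile.normalized_coverage or profile.raw_coverage
    for rid in (host_id, virus_id):
        if rid not in cov:
            raise KeyError(f"reference {rid!r} missing from profile {profile.sample_id}")
    if cov[virus_id] == 0:
        return None
    return cov[host_id] / cov[virus_id]


@dataclass
class DynamicsReport:
    """Per-sample spacer and host-virus statistics across timepoints."""

    samples: pd.DataFrame  # indexed by sample_id
    per_virus: pd.DataFrame  # one row per (sample_id, virus_id)


def spacer_dynamics(
    clusters: list[SpacerCluster],
    matches: list[ProtospacerMatch],
    profiles: list[SampleProfile],
    host_id: str,
    virus_ids: list[str] | None = None,
    min_presence: int = 2,
) -> DynamicsReport:
    """Temporal spacer-diversification statistics.

    Spacer abundances are normalized by each sample's host coverage
    relative to the minimum host coverage across samples (counts from a
    sample with twice the host are halved); distinct-cluster and
    singleton counts stay un-normalized. Per-virus statistics cover the
    clusters with a protospacer match to that virus. Singletons are
    clusters with exactly one occurrence across the whole sample set.

    A cluster counts toward ``distinct_matching_clusters`` in a sample
    when it has at least ``min_presence`` occurrences there (default 2):
    genuine spacers are sampled tens of times per sample while clusters
    born from a single sequencing error are seen once, so the
    seen-more-than-once rule separates repertoire from read noise. The
    unfiltered count is reported alongside as
    ``distinct_matching_clusters_raw``.
    """
    sample_ids = [p.sample_id for p in profiles]
    cluster_samples = set()
    for cl in clusters:
        cluster_samples.update(cl.member_count_per_sample)
    unknown = cluster_samples - set(sample_ids)
    if unknown:
        raise ValueError(f"cluster counts reference unknown samples: {sorted(unknown)}")
    cov = {
        p.sample_id: (p.normalized_coverage or p.raw_coverage)[host_id]
        for p in profiles
    }
    if any(c <= 0 for c in cov.values()):
        raise ValueError("host coverage must be positive in every sample")
    min_cov = min(cov.values())
    factor = {s: cov[s] / min_cov for s in sample_ids}

    if virus_ids is None:
        virus_ids = sorted({m.scaffold_id for m in matches})
    virus_clusters: dict[str, set[str]] = {v: set() for v in virus_ids}
    for m in matches:
        if m.scaffold_id in virus_clusters:
            virus_clusters[m.scaffold_id].add(m.cluster_id)

    rows = []
    virus_rows = []
    for p in profiles:
        s = p.sample_id
        total = sum(cl.member_count_per_sample.get(s, 0) for cl in clusters)
        distinct = sum(1 for cl in clusters if cl.member_count_per_sample.get(s, 0) > 0)
        singletons = sum(
            1
            for cl in clusters
            if cl.is_singleton and cl.member_count_per_sample.get(s, 0) == 1
        )
        rows.append(
            {
                "sample_id": s,
                "host_normalized_coverage": cov[s],
                "spacer_abundance_raw": total,
                "spacer_abundance_norm": total / factor[s],
                "distinct_spacer_clusters": distinct,
                "singleton_spacer_clusters": singletons,
            }
        )
        for v in virus_ids:
            cls = virus_clusters[v]
            v_total = sum(
                cl.member_count_per_sample.get(s, 0)
                for cl in clusters
                if cl.cluster_id in cls
            )
            v_distinct = sum(
                1
                for cl in clusters
                if cl.cluster_id in cls
                and cl.member_count_per_sample.get(s, 0) >= min_presence
            )
            v_distinct_raw = sum(
                1
                for cl in clusters
                if cl.cluster_id in cls and cl.member_count_per_sample.get(s, 0) > 0
            )
            virus_rows.append(
                {
                    "sample_id": s,
                    "virus_id": v,
                    "matching_abundance_raw": v_total,
                    "matching_abundance_norm": v_total / factor[s],
                    "distinct_matching_clusters": v_distinct,
                    "distinct_matching_clusters_raw": v_distinct_raw,
                    "host_virus_ratio": host_virus_ratio(p, host_id, v)
                    if v in p.ref_lengths
                    else math.nan,
                }
            )
    samples_df = pd.DataFrame(rows).set_index("sample_id")
    per_virus_df = pd.DataFrame(
        virus_rows,
        columns=[
            "sample_id",
            "virus_id",
            "matching_abundance_raw",
            "matching_abundance_norm",
            "distinct_matching_clusters",
            "distinct_matching_clusters_raw",
            "host_virus_ratio",
        ],
    )
    return DynamicsReport(samples_df, per_virus_df)
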