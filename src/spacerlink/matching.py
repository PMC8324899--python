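"""Spacer-cluster-to-scaffold protospacer matching.

Cluster representatives (not all members) are searched against candidate
scaffolds with the short-query seeded local aligner; a hit is retained
when its similarity — identical bases divided by the full spacer length,
the conservative denominator that penalizes partial-length local hits —
reaches the acceptance threshold (default 0.80, inclusive). The
denominator is configurable ("query" or "alignment").

Because the +1/-3 local scoring clips mismatch-dense spacer ends out of
the optimal HSP, similarity under the "query" denominator is counted
over the HSP extended ungapped to full spacer coverage at its locus
(clamped at scaffold bounds); a spacer whose protospacer carries exactly
20% substitutions therefore still scores similarity 0.80 and sits on the
inclusive boundary.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .align import LocalAlignment, Scoring, DEFAULT_SCORING, seed_and_extend
from .clustering import SpacerCluster
from .sequtils import revcomp


@dataclass
class ProtospacerMatch:
    cluster_id: str
    scaffold_id: str
    scaffold_start: int  # 0-based half-open on the scaffold forward strand
    scaffold_end: int
    strand: str
    aligned_length: int  # scaffold_end - scaffold_start
    identities: int
    similarity: float
    spacer_abundance: Counter = field(default_factory=Counter)  # per sample


def _full_query_span(
    query: str, subject: str, aln: LocalAlignment
) -> tuple[int, int, int]:
    """Extend an HSP ungapped to full query coverage at its locus.

    Returns (identities, s_start, s_end) with the subject span clamped to
    the scaffold bounds; unaligned query overhangs beyond a scaffold end
    count as non-identical.
    """
    q = query if aln.strand == "+" else revcomp(query)
    if aln.strand == "+":
        qs, qe = aln.q_start, aln.q_end
    else:
        qs, qe = len(query) - aln.q_end, len(query) - aln.q_start
    identities = aln.matches
    left_q = q[:qs]
    ls = subject[max(0, aln.s_start - len(left_q)) : aln.s_start]
    identities += sum(a == b for a, b in zip(left_q[len(left_q) - len(ls) :], ls))
    right_q = q[qe:]
    rs = subject[aln.s_end : aln.s_end + len(right_q)]
    identities += sum(a == b for a, b in zip(right_q, rs))
    return identities, aln.s_start - len(ls), aln.s_end + len(rs)


def match_clusters_to_scaffolds(
    clusters: list[SpacerCluster],
    scaffolds: list[tuple[str, str]],
    min_similarity: float = 0.80,
    word_size: int = 7,
    sim_denominator: str = "query",
    scoring: Scoring = DEFAULT_SCORING,
) -> list[ProtospacerMatch]:
    """All (cluster, scaffold, locus) alignments at or above *min_similarity*."""
    if sim_denominator not in ("query", "alignment"):
        raise ValueError("sim_denominator must be 'query' or 'alignment'")
    if not 0.0 < min_similarity <= 1.0:
        raise ValueError(f"min_similarity must be in (0, 1], got {min_similarity}")
    out: list[ProtospacerMatch] = []
    for cl in clusters:
        rep = cl.representative
        for sc_id, sc_seq in scaffolds:
            found: list[ProtospacerMatch] = []
            for aln in seed_and_extend(
                rep,
                sc_seq,
                word_size=word_size,
                scoring=scoring,
                prefilter_min_ungapped=2 * word_size - 1,
            ):
                if sim_denominator == "query":
                    identities, s_start, s_end = _full_query_span(rep, sc_seq, aln)
                    sim = identities / len(rep)
                else:
                    identities, s_start, s_end = aln.matches, aln.s_start, aln.s_end
                    sim = identities / aln.aligned_len if aln.aligned_len else 0.0
                if sim >= min_similarity:
                    found.append(
                        ProtospacerMatch(
                            cl.cluster_id,
                            sc_id,
                            s_start,
                            s_end,
                            aln.strand,
                            s_end - s_start,
                            identities,
                            sim,
                            Counter(cl.member_count_per_sample),
                        )
                    )
            # extension can make neighbouring HSP loci coincide; keep the best
            found.sort(key=lambda m: (-m.similarity, m.scaffold_start))
            kept: list[ProtospacerMatch] = []
            for m in found:
                span = m.scaffold_end - m.scaffold_start
                if all(
                    min(m.scaffold_end, k.scaffold_end)
                    - max(m.scaffold_start, k.scaffold_start)
                    <= 0.5 * min(span, k.scaffold_end - k.scaffold_start)
                    for k in kept
                ):
                    kept.append(m)
            out.extend(kept)
    return out


def summarize_linkage(
    matches: list[ProtospacerMatch], scaffolds: list[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Per-scaffold linkage evidence table.

    One row per spacer-targeted scaffold: number of distinct matching
    clusters, distinct protospacer loci, and total matching spacer
    abundance per sample (columns ``abundance_<sample>``).
    """
    rows: dict[str, dict] = {}
    for m in matches:
        row = rows.setdefault(
            m.scaffold_id,
            {"scaffold_id": m.scaffold_id, "clusters": set(), "loci": set(),
             "abundance": Counter()},
        )
        row["clusters"].add(m.cluster_id)
        row["loci"].add((m.scaffold_start, m.scaffold_end, m.strand))
        row["abundance"].update(m.spacer_abundance)
    records = []
    for sc_id in sorted(rows):
        row = rows[sc_id]
        rec = {
            "scaffold_id": sc_id,
            "n_matching_clusters": len(row["clusters"]),
            "n_protospacer_loci": len(row["loci"]),
        }
        for sample, count in sorted(row["abundance"].items()):
            rec[f"abundance_{sample}"] = count
        records.append(rec)
    df = pd.DataFrame(records)
    if df.empty:
        df = pd.DataFrame(
            columns=["scaffold_id", "n_matching_clusters", "n_protospacer_loci"]
        )
    return df.fillna(0)


def spacer_targeted_ids(matches: list[ProtospacerMatch]) -> set[str]:
    return {m.scaffold_id for m in matches}
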