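"""Viral scaffold classification and species/genus demarcation.

Spacer-targeted scaffolds are screened through an ordered rule set
reconstructing the study's decision scheme from its stated outcomes:

1. length <= min_len (3 kb)                      -> not_considered
2. extensive CRISPR array (>= 5 spacers)         -> rejected (false positive)
3. bacterial evidence without any hallmark gene  -> rejected
4. hallmark gene(s) AND circular                 -> virus
5. spacer-targeted                               -> putative_virus
6. otherwise                                     -> not_considered

Hallmark/VOG/bacterial evidence arrives as an annotation table (gene
prediction and database searches are deliberately external); circularity
and mini-CRISPR arrays are detected from sequence. The exact decision
nodes of the original scheme are not published in full; this rule order
is a documented reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

import edlib

from .clustering import _CIGAR_RE


@dataclass
class ScaffoldFeatures:
    scaffold_id: str
    length: int
    is_circular: bool = False
    terminal_repeat_len: int = 0
    hallmark_gene_count: int = 0
    vog_hit_count: int = 0
    bacterial_hit_count: int = 0
    crispr_array_spacer_count: int = 0
    spacer_targeted: bool = False
    lytic_category: str | None = None  # external VirSorter-style passthrough

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.scaffold_id}: length must be positive")
        for name in (
            "hallmark_gene_count",
            "vog_hit_count",
            "bacterial_hit_count",
            "crispr_array_spacer_count",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.scaffold_id}: {name} must be >= 0")


@dataclass
class Classification:
    scaffold_id: str
    verdict: str  # virus | putative_virus | rejected | not_considered
    reasons: list[str] = field(default_factory=list)


def detect_circularity(
    sequence: str, min_repeat: int = 20, max_repeat: int = 500
) -> tuple[bool, int, int]:
    """Terminal-direct-repeat circularity test.

    The longest exact prefix that equals a suffix (length >= min_repeat,
    search capped at min(len/2, max_repeat)) marks an assembly of a
    circular replicon; returns (is_circular, repeat_len, trimmed_length).
    """
    n = len(sequence)
    cap = min(n // 2, max_repeat)
    for k in range(cap, min_repeat - 1, -1):
        if sequence[:k] == sequence[n - k :]:
            return True, k, n - k
    return False, 0, n


@dataclass
class MiniCrisprArray:
    start: int
    end: int
    repeat: str
    n_spacers: int


def detect_mini_crispr(
    sequence: str,
    repeat_len_range: tuple[int, int] = (23, 50),
    spacer_len_range: tuple[int, int] = (20, 60),
    min_units: int = 2,
) -> list[MiniCrisprArray]:
    """Find runs of >= min_units exact repeat copies separated by spacers.

    Anchors on exact k-mer recurrences (k = minimum repeat length) at
    CRISPR-like spacing, extends the anchor pair to the maximal shared
    repeat, then walks downstream collecting further units. Random
    sequence essentially never anchors (a recurring 23-mer at 43-110 bp
    spacing).
    """
    k = repeat_len_range[0]
    r_lo, r_hi = repeat_len_range
    s_lo, s_hi = spacer_len_range
    period_lo, period_hi = r_lo + s_lo, r_hi + s_hi
    n = len(sequence)
    if n < 2 * k + s_lo:
        return []
    positions: dict[str, int] = {}
    candidates: list[tuple[int, int]] = []  # (first_pos, second_pos) anchor pairs
    for i in range(n - k + 1):
        word = sequence[i : i + k]
        j = positions.get(word)
        if j is not None and period_lo <= i - j <= period_hi:
            candidates.append((j, i))
        positions[word] = i

    arrays: list[MiniCrisprArray] = []
    covered: list[tuple[int, int]] = []
    for p, q in candidates:
        if any(a <= p < b for a, b in covered):
            continue
        word = sequence[p : p + k]
        # walk downstream collecting further exact copies of the anchor word
        # at CRISPR-like spacing, then derive the full repeat as the minimal
        # common left/right extension across all collected units
        units = [p, q]
        while True:
            prev = units[-1]
            nxt = next(
                (
                    x
                    for x in range(prev + period_lo, min(prev + period_hi, n - k) + 1)
                    if sequence[x : x + k] == word
                ),
                None,
            )
            if nxt is None:
                break
            units.append(nxt)
        pairs = list(zip(units, units[1:]))
        left = 0
        while all(
            u - left - 1 >= 0 and sequence[u - left - 1] == sequence[v - left - 1]
            for u, v in pairs
        ) and k + left < r_hi:
            left += 1
        right = 0
        while all(
            v + k + right < n and sequence[u + k + right] == sequence[v + k + right]
            for u, v in pairs
        ) and k + left + right < r_hi:
            right += 1
        r_len = k + left + right
        starts = [u - left for u in units]
        spacer_ok = [
            s_lo <= b - (a + r_len) <= s_hi for a, b in zip(starts, starts[1:])
        ]
        if not all(spacer_ok):
            continue
        if len(starts) >= min_units:
            end = starts[-1] + r_len
            arrays.append(
                MiniCrisprArray(starts[0], end, sequence[starts[0] : starts[0] + r_len], len(starts) - 1)
            )
            covered.append((starts[0], end))
    return arrays


def classify(
    features: ScaffoldFeatures,
    min_len: int = 3000,
    extensive_crispr: int = 5,
    bacterial_evidence: int = 3,
) -> Classification:
    """Apply the ordered classification rules; total over all inputs."""
    sid = features.scaffold_id
    if features.length <= min_len:
        return Classification(sid, "not_considered", ["length_gate"])
    if features.crispr_array_spacer_count >= extensive_crispr:
        return Classification(sid, "rejected", ["extensive_crispr_array"])
    if features.bacterial_hit_count >= bacterial_evidence and features.hallmark_gene_count == 0:
        return Classification(sid, "rejected", ["bacterial_no_hallmark"])
    if features.hallmark_gene_count >= 1 and features.is_circular:
        return Classification(sid, "virus", ["hallmark_genes", "circular"])
    if features.spacer_targeted:
        return Classification(sid, "putative_virus", ["spacer_targeted"])
    return Classification(sid, "not_considered", ["no_evidence"])


def features_from_inputs(
    scaffolds: list[tuple[str, str]],
    annotations: pd.DataFrame | None = None,
    spacer_targeted: set[str] | None = None,
) -> list[ScaffoldFeatures]:
    """Assemble ScaffoldFeatures from sequences, an annotation table and linkage.

    The annotation table has one row per gene with columns gene_id,
    scaffold_id, is_hallmark, is_vog_hit, is_bacterial (booleans or 0/1).
    """
    spacer_targeted = spacer_targeted or set()
    counts: dict[str, dict[str, int]] = {}
    if annotations is not None and len(annotations):
        for col in ("is_hallmark", "is_vog_hit", "is_bacterial"):
            if col not in annotations.columns:
                raise ValueError(f"annotation table is missing column {col!r}")
        grouped = annotations.groupby("scaffold_id")[
            ["is_hallmark", "is_vog_hit", "is_bacterial"]
        ].sum()
        counts = {str(k): v for k, v in grouped.astype(int).to_dict("index").items()}
    out = []
    for sc_id, seq in scaffolds:
        circ, tr_len, _ = detect_circularity(seq)
        arrays = detect_mini_crispr(seq)
        ann = counts.get(sc_id, {})
        out.append(
            ScaffoldFeatures(
                scaffold_id=sc_id,
                length=len(seq),
                is_circular=circ,
                terminal_repeat_len=tr_len,
                hallmark_gene_count=int(ann.get("is_hallmark", 0)),
                vog_hit_count=int(ann.get("is_vog_hit", 0)),
                bacterial_hit_count=int(ann.get("is_bacterial", 0)),
                crispr_array_spacer_count=sum(a.n_spacers for a in arrays),
                spacer_targeted=sc_id in spacer_targeted,
            )
        )
    return out


def _anchor_regions(a: str, b: str, word_size: int, band: int):
    """Diagonal-grouped exact word anchors between two genomes."""
    index: dict[str, list[int]] = {}
    for i in range(0, len(a) - word_size + 1):
        index.setdefault(a[i : i + word_size], []).append(i)
    groups: dict[int, list[tuple[int, int]]] = {}
    for j in range(0, len(b) - word_size + 1):
        for i in index.get(b[j : j + word_size], ()):
            d = (j - i) // band  # coarse diagonal bucket
            groups.setdefault(d, []).append((i, j))
    return groups


def intergenomic_similarity(
    genome_a: str, genome_b: str, word_size: int = 15, band: int = 100
) -> float:
    """Whole-genome nucleotide similarity in percent.

    similarity = 100 * 2 * (identical bases over the aligned regions) /
    (len_a + len_b). Alignable regions are located by exact word anchors
    grouped by diagonal; each group's spanned region (snapped to the
    sequence bounds when the unanchored tail is short) is globally
    aligned and its identical bases counted. Unrelated genomes share no
    anchor and score 0. Symmetric; 100 iff the sequences are identical.
    """
    if not genome_a or not genome_b:
        raise ValueError("empty genome")
    if genome_a == genome_b:
        return 100.0
    la, lb = len(genome_a), len(genome_b)
    if min(la, lb) < word_size:
        return 0.0
    groups = _anchor_regions(genome_a, genome_b, word_size, band)
    if not groups:
        return 0.0
    # largest groups first; count each genome region once
    used_a: list[tuple[int, int]] = []
    used_b: list[tuple[int, int]] = []
    total_matches = 0
    tail = 500  # snap region ends to genome bounds across short unanchored tails
    for d in sorted(groups, key=lambda d: -len(groups[d])):
        anchors = groups[d]
        a0 = min(i for i, _ in anchors)
        a1 = max(i for i, _ in anchors) + word_size
        b0 = min(j for _, j in anchors)
        b1 = max(j for _, j in anchors) + word_size
        if a0 <= tail and b0 <= tail:
            shift = min(a0, b0)
            a0, b0 = a0 - shift, b0 - shift
        if la - a1 <= tail and lb - b1 <= tail:
            shift = min(la - a1, lb - b1)
            a1, b1 = a1 + shift, b1 + shift
        if any(a0 < e and s < a1 for s, e in used_a) or any(
            b0 < e and s < b1 for s, e in used_b
        ):
            continue
        used_a.append((a0, a1))
        used_b.append((b0, b1))
        res = edlib.align(genome_a[a0:a1], genome_b[b0:b1], mode="NW", task="path")
        total_matches += sum(
            int(n) for n, op in _CIGAR_RE.findall(res["cigar"] or "") if op == "="
        )
    return 100.0 * 2.0 * total_matches / (la + lb)


def similarity_matrix(genomes: list[tuple[str, str]], **kwargs) -> pd.DataFrame:
    ids = [g[0] for g in genomes]
    mat = pd.DataFrame(np.zeros((len(ids), len(ids))), index=ids, columns=ids)
    for i, (_, a) in enumerate(genomes):
        mat.iloc[i, i] = 100.0
        for j in range(i + 1, len(ids)):
            s = intergenomic_similarity(a, genomes[j][1], **kwargs)
            mat.iloc[i, j] = s
            mat.iloc[j, i] = s
    return mat


def demarcate(
    sim: pd.DataFrame,
    species_threshold: float = 95.0,
    genus_threshold: float = 15.8,
) -> tuple[dict[str, int], dict[str, int]]:
    """Single-linkage species and genus clusters from a similarity matrix.

    Returns (species, genus) mappings genome id -> cluster index. Species
    clusters refine genus clusters because single linkage is monotone in
    the threshold.
    """
    values = sim.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1] or not np.allclose(values, values.T):
        raise ValueError("similarity matrix must be square and symmetric")
    ids = list(sim.index)

    def _cut(threshold: float) -> dict[str, int]:
        adj = csr_matrix(values >= threshold)
        _, labels = connected_components(adj, directed=False)
        return dict(zip(ids, (int(x) for x in labels)))

    return _cut(species_threshold), _cut(genus_threshold)
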