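"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (regex scans, full dynamic
programming with plain Python loops) and shares no code with the package
paths it checks.
"""

from __future__ import annotations

import re

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def regex_dr_occurrences(read: str, dr: str) -> list[tuple[int, int, str]]:
    """All (start, end, strand) exact DR occurrences via regex lookahead."""
    hits = []
    for pattern, strand in ((dr, "+"), (rc(dr), "-")):
        if strand == "-" and pattern == dr:
            break
        for m in re.finditer(f"(?=({re.escape(pattern)}))", read):
            hits.append((m.start(), m.start() + len(pattern), strand))
    hits.sort(key=lambda h: (h[0], h[2]))
    return hits


def regex_split_spacers(
    read: str, dr: str, min_len: int = 20, max_len: int = 60
) -> list[str]:
    """Brute-force regex splitter: canonical spacers between same-strand DRs."""
    hits = regex_dr_occurrences(read, dr)
    fwd = [h for h in hits if h[2] == "+"]
    rev = [h for h in hits if h[2] == "-"]
    chosen, strand = (fwd, "+") if len(fwd) >= len(rev) else (rev, "-")
    out = []
    for (s1, e1, _), (s2, e2, _) in zip(chosen, chosen[1:]):
        if s2 < e1:
            continue
        spacer = read[e1:s2]
        if min_len <= len(spacer) <= max_len:
            out.append(spacer if strand == "+" else rc(spacer))
    return out


def smith_waterman(
    query: str,
    subject: str,
    match: int = 1,
    mismatch: int = -3,
    gap_open: int = -5,
    gap_extend: int = -2,
):
    """Exhaustive affine local alignment (plain loops, full traceback).

    A length-k gap costs gap_open + k * gap_extend. Returns
    (score, q_start, q_end, s_start, s_end, matches) of the optimum, or
    None when no positive cell exists; ties resolve to the end cell first
    in row-major order, matching the package convention.
    """
    m, n = len(query), len(subject)
    NEG = -(10**9)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        qi = query[i - 1]
        Hi, Hp, Ei, Fi, Fp = H[i], H[i - 1], E[i], F[i], F[i - 1]
        for j in range(1, n + 1):
            e = max(Ei[j - 1] + gap_extend, Hi[j - 1] + gap_open + gap_extend)
            f = max(Fp[j] + gap_extend, Hp[j] + gap_open + gap_extend)
            s = match if qi == subject[j - 1] else mismatch
            h = max(0, Hp[j - 1] + s, e, f)
            Ei[j], Fi[j], Hi[j] = e, f, h
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0:
        return None
    # traceback
    i, j, state, matches = bi, bj, "H", 0
    while True:
        if state == "H":
            v = H[i][j]
            if v == 0:
                break
            s = match if query[i - 1] == subject[j - 1] else mismatch
            if v == H[i - 1][j - 1] + s:
                matches += query[i - 1] == subject[j - 1]
                i, j = i - 1, j - 1
            elif v == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            if E[i][j] == E[i][j - 1] + gap_extend:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:
            if F[i][j] == F[i - 1][j] + gap_extend:
                i -= 1
            else:
                i -= 1
                state = "H"
    return best, i, bi, j, bj, matches


def max_match_identity(a: str, b: str) -> float:
    """Matches in the match-maximizing global alignment / shorter length.

    Gap and mismatch cost nothing in the count, so the match count is the
    longest common subsequence.
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    prev = [0] * (len(long_) + 1)
    for ch in short:
        cur = [0] * (len(long_) + 1)
        for j, cl in enumerate(long_, 1):
            cur[j] = max(prev[j], cur[j - 1], prev[j - 1] + (ch == cl))
        prev = cur
    return prev[-1] / len(short)


def semiglobal_identity(a: str, b: str) -> float:
    """Matches in the minimum-edit-distance end-gap-free alignment / shorter.

    The shorter sequence aligns end to end, overhangs of the longer are
    free; the alignment minimizes Levenshtein distance and the match
    count is read off its traceback (diagonal moves preferred). Plain
    O(nm) Python loops, independent of any alignment library.
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    m, n = len(short), len(long_)
    D = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        D[i][0] = i
        row, prev = D[i], D[i - 1]
        ci = short[i - 1]
        for j in range(1, n + 1):
            row[j] = min(
                prev[j - 1] + (ci != long_[j - 1]),
                prev[j] + 1,
                row[j - 1] + 1,
            )
    # free end gaps in the longer sequence: best column in the last row
    j = min(range(n + 1), key=lambda j: D[m][j])
    i, matches = m, 0
    while i > 0:
        if j > 0 and D[i][j] == D[i - 1][j - 1] + (short[i - 1] != long_[j - 1]):
            matches += short[i - 1] == long_[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and D[i][j] == D[i - 1][j] + 1:
            i -= 1
        else:
            j -= 1
    return matches / m


def brute_force_clusters(
    seq_counts: dict[str, int], threshold: float = 0.99
) -> list[tuple[str, set[str]]]:
    """Greedy clustering with the oracle identity; returns (rep, members)."""
    clusters: list[tuple[str, set[str]]] = []
    for seq in sorted(seq_counts, key=lambda s: (-len(s), s)):
        for rep, members in clusters:
            if semiglobal_identity(seq, rep) >= threshold:
                members.add(seq)
                break
        else:
            clusters.append((seq, {seq}))
    return clusters
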