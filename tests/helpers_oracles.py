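"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive results by exhaustive search / textbook
dynamic programming, sharing no code with the implementation they check.
"""

from __future__ import annotations

NEG = float("-inf")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def oracle_merge(
    r1: str, r2: str, min_overlap: int, max_mismatch_frac: float
) -> tuple[int, int] | None:
    """Exhaustive overlap search between r1's 3' end and revcomp(r2)'s
    5' end: minimise mismatch fraction, break ties by longer overlap.
    Returns (overlap_length, mismatches) or None."""
    rc2 = oracle_revcomp(r2)
    candidates = []
    for length in range(min_overlap, min(len(r1), len(rc2)) + 1):
        tail = r1[len(r1) - length :]
        head = rc2[:length]
        mism = sum(a != b for a, b in zip(tail, head))
        candidates.append((mism / length, -length, mism))
    if not candidates:
        return None
    frac, neg_l, mism = min(candidates)
    if frac > max_mismatch_frac:
        return None
    return -neg_l, mism


def oracle_fit_score(
    reference: str,
    read: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -8.0,
    gap_extend: float = -1.0,
) -> float:
    """Affine-gap fit alignment score by explicit three-state dynamic
    programming (Gotoh): the read aligns globally, reference end
    overhangs are free. A length-L gap costs ``gap_open +
    (L-1)*gap_extend``; reference overhangs before the first or after
    the last read base cost nothing.
    """
    t, q = reference, read
    m, n = len(t), len(q)
    # state 0: last column consumed both (match/mismatch)
    # state 1: gap in read row, reference consumed (deletion)
    # state 2: gap in reference row, read consumed (insertion)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    D = [[NEG] * (n + 1) for _ in range(m + 1)]
    I = [[NEG] * (n + 1) for _ in range(m + 1)]
    M[0][0] = 0.0
    for j in range(1, n + 1):
        I[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, m + 1):
        D[i][0] = 0.0  # free left reference overhang
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if t[i - 1] == q[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], D[i - 1][j - 1],
                          I[i - 1][j - 1]) + s
            if j == n:  # free right reference overhang
                d_open, d_ext = 0.0, 0.0
            else:
                d_open, d_ext = gap_open, gap_extend
            D[i][j] = max(
                M[i - 1][j] + d_open,
                I[i - 1][j] + d_open,
                D[i - 1][j] + d_ext,
            )
            I[i][j] = max(
                M[i][j - 1] + gap_open,
                D[i][j - 1] + gap_open,
                I[i][j - 1] + gap_extend,
            )
    return max(M[m][n], D[m][n], I[m][n])


def oracle_anova_f(groups: list[list[float]]) -> float:
    """One-way ANOVA F statistic from first principles."""
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(
        (v - sum(g) / len(g)) ** 2 for g in groups for v in g
    )
    dfb = len(groups) - 1
    dfw = len(all_vals) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


def oracle_self_complement_runs(seq: str, run: int) -> list[tuple[int, int]]:
    """All (i, j) window pairs, i < j, where seq[i:i+run] could base-pair
    antiparallel with seq[j:j+run]."""
    hits = []
    n = len(seq)
    for i in range(n - run + 1):
        target = oracle_revcomp(seq[i : i + run])
        for j in range(i + 1, n - run + 1):
            if seq[j : j + run] == target:
                hits.append((i, j))
    return hits
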