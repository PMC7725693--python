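"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately share no code with the package: pure-Python scans,
exact rational arithmetic and recursive clustering, kept slow and
obvious.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def iupac_prefix_mismatches(read: str, primer: str) -> int:
    """Per-position mismatch count of a primer against a read prefix."""
    if len(read) < len(primer):
        return len(primer)
    return sum(
        1 for p, r in zip(primer, read) if r not in IUPAC[p]
    )


def naive_merge(fwd, rc_rev, fwd_qual, rc_rev_qual, min_overlap, max_density):
    """Exhaustive-offset pair merge; returns (sequence, offset) or None.

    Scans every offset of the reverse-complemented mate's start within
    the forward mate, scores all admissible offsets, and applies the
    longest-overlap / fewest-mismatch / smallest-offset preference by
    sorting, not by early exit.
    """
    lf, lr = len(fwd), len(rc_rev)
    candidates = []
    for o in range(0, lf + 1):
        ov = min(lf - o, lr)
        if ov < min_overlap:
            continue
        mism = sum(1 for i in range(ov) if fwd[o + i] != rc_rev[i])
        if mism <= max_density * ov:
            candidates.append((-ov, mism, o))
    if not candidates:
        return None
    _, _, o = min(candidates)
    ov = min(lf - o, lr)
    out = list(fwd[:o])
    for i in range(ov):
        f, r = fwd[o + i], rc_rev[i]
        if f == r:
            out.append(f)
        elif rc_rev_qual[i] > fwd_qual[o + i]:
            out.append(r)
        else:
            out.append(f)
    if o + lr > lf:
        out.extend(rc_rev[ov:])
    else:
        out.extend(fwd[o + lr:])
    return "".join(out), o


def naive_fisher(table) -> Fraction:
    """Two-sided Fisher exact p by full enumeration in exact rationals."""
    (a, b), (c, d) = table
    row1, col1, total = a + b, a + c, a + b + c + d
    denom = comb(total, row1)
    p_obs = Fraction(comb(col1, a) * comb(total - col1, row1 - a), denom)
    p = Fraction(0)
    for k in range(max(0, row1 + col1 - total), min(row1, col1) + 1):
        pk = Fraction(comb(col1, k) * comb(total - col1, row1 - k), denom)
        if pk <= p_obs:
            p += pk
    return min(p, Fraction(1))


def naive_complete_linkage_heights(d) -> list[float]:
    """Merge heights of complete-linkage clustering, via frozensets.

    Tie-free inputs give a unique dendrogram, so the sorted height list
    identifies it together with the cophenetic structure below.
    """
    n = len(d)
    clusters = [frozenset([i]) for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = max(d[a][b] for a in clusters[i] for b in clusters[j])
                if best is None or h < best[0]:
                    best = (h, i, j)
        h, i, j = best
        heights.append(h)
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return heights


def naive_cophenetic(d) -> dict[tuple[int, int], float]:
    """Pairwise cophenetic heights from the recursive clustering above."""
    n = len(d)
    clusters = [frozenset([i]) for i in range(n)]
    coph: dict[tuple[int, int], float] = {}
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = max(d[a][b] for a in clusters[i] for b in clusters[j])
                if best is None or h < best[0]:
                    best = (h, i, j)
        h, i, j = best
        for a in clusters[i]:
            for b in clusters[j]:
                coph[(min(a, b), max(a, b))] = h
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return coph


def naive_chi_squared(table) -> float:
    """Pearson statistic by direct summation over cells."""
    rows = len(table)
    cols = len(table[0])
    total = sum(sum(r) for r in table)
    row_sums = [sum(r) for r in table]
    col_sums = [sum(table[i][j] for i in range(rows)) for j in range(cols)]
    stat = 0.0
    for i in range(rows):
        for j in range(cols):
            e = row_sums[i] * col_sums[j] / total
            stat += (table[i][j] - e) ** 2 / e
    return stat
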