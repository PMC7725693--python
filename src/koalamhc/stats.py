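"""Population-level analysis of multi-locus MHC profiles.

Profiles are encoded as binary allele-presence vectors; on symmetric
binary attributes with equal weights, Gower's similarity coefficient
reduces to simple matching, so the dissimilarity used for clustering is
the fraction of (locus, allele) columns on which two koalas differ.
Clustering is agglomerative with complete linkage.  Allele–phenotype
association uses the two-sided Fisher exact test; haplotype-group
heterogeneity uses the Pearson chi-squared test.  p-values are reported
raw — no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2_contingency, hypergeom

from .genotype import NO_DATA, KoalaProfile


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves away from zero (62.5 -> 63)."""
    import math

    return int(math.floor(x + 0.5))


def build_presence_matrix(profiles: Sequence[KoalaProfile]) -> pd.DataFrame:
    """Binary allele-presence matrix: rows = koalas, columns = ``LOCUS*ALLELE``.

    Columns are the sorted union of observed (locus, allele) pairs, so
    the encoding is deterministic.  NO_DATA loci contribute no columns
    (and code 0 in the columns other koalas define).
    """
    if not profiles:
        raise ValueError("no profiles given")
    pairs: set[tuple[str, str]] = set()
    for p in profiles:
        for locus, calls in p.calls.items():
            if calls is not NO_DATA:
                pairs.update((locus, a) for a in calls)
    columns = [f"{locus}*{allele}" for locus, allele in sorted(pairs)]
    data = np.zeros((len(profiles), len(columns)), dtype=np.int8)
    col_idx = {c: i for i, c in enumerate(columns)}
    for i, p in enumerate(profiles):
        for locus, calls in p.calls.items():
            if calls is not NO_DATA:
                for allele in calls:
                    data[i, col_idx[f"{locus}*{allele}"]] = 1
    return pd.DataFrame(data, index=[p.individual for p in profiles], columns=columns)


def gower_dissimilarity(matrix: pd.DataFrame) -> np.ndarray:
    """Pairwise simple-matching distance between presence rows.

    d(i, j) = (# columns where i and j differ) / (# columns); symmetric,
    zero diagonal, values in [0, 1].
    """
    if len(matrix) < 2:
        raise ValueError("need at least two individuals")
    return squareform(pdist(matrix.to_numpy(dtype=float), metric="hamming"))


def complete_linkage(d: np.ndarray) -> np.ndarray:
    """Agglomerative complete-linkage clustering of a dissimilarity matrix.

    Returns a linkage matrix in the usual (n-1, 4) layout: each row is
    ``[id_a, id_b, height, size]`` with original points numbered 0..n-1
    and the cluster formed at step k numbered n+k.  At each step the
    active pair at minimum distance merges; ties break on the lowest
    (id_a, id_b) pair.  Cluster-to-cluster distance is the maximum
    pairwise point distance, so merge heights are non-decreasing.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    n = d.shape[0]
    active: dict[int, np.ndarray] = {}  # cluster id -> distances to others
    dist: dict[tuple[int, int], float] = {}
    ids = list(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d[i, j]
    sizes = {i: 1 for i in range(n)}
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        Z[step] = [a, b, h, sizes[a] + sizes[b]]
        sizes[next_id] = sizes.pop(a) + sizes.pop(b)
        ids.remove(a)
        ids.remove(b)
        for k in ids:
            da = dist.pop((min(a, k), max(a, k)))
            db = dist.pop((min(b, k), max(b, k)))
            dist[(k, next_id)] = max(da, db)
        dist.pop((a, b))
        ids.append(next_id)
        next_id += 1
    return Z


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a linkage matrix as a Newick string.

    Branch lengths are the difference between a node's merge height and
    its parent's, so root-to-leaf path lengths equal merge heights.
    """
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        left = f"{nodes[a]}:{h - heights[a]:.6g}"
        right = f"{nodes[b]}:{h - heights[b]:.6g}"
        nodes[n + k] = f"({left},{right})"
        heights[n + k] = h
    return nodes[n + len(Z) - 1] + ";"


def linkage_table(Z: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(Z, columns=["cluster_a", "cluster_b", "height", "size"])


# ---------------------------------------------------------------------------
# Association tests


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 integer table.

    p is the sum of hypergeometric probabilities, over all tables with
    the observed margins, that do not exceed the observed table's
    probability (with relative slack 1e-7 in the comparison) — the
    convention of the common statistics ecosystems.  Counts up to a few
    hundred use exact integer binomials; larger tables fall back to the
    scipy hypergeometric pmf.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("negative cell count")
    row1 = int(t[0].sum())
    col1 = int(t[:, 0].sum())
    total = int(t.sum())
    if total == 0:
        return 1.0
    lo = max(0, row1 + col1 - total)
    hi = min(row1, col1)
    support = range(lo, hi + 1)
    if total <= 500:
        from math import comb

        denom = comb(total, row1)
        weights = {
            k: comb(col1, k) * comb(total - col1, row1 - k) for k in support
        }
        w_obs = weights[int(t[0, 0])]
        # integer comparison with the same 1e-7 relative slack, kept exact
        p = sum(w for w in weights.values() if w * 10**7 <= w_obs * (10**7 + 1))
        return float(min(1.0, p / denom))
    rv = hypergeom(total, col1, row1)
    pmf = rv.pmf(np.asarray(support))
    p_obs = rv.pmf(int(t[0, 0]))
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def chi_squared_test(table: Sequence[Sequence[int]]) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence: (statistic, df, p).

    Expected counts come from the margin products; df = (rows-1)(cols-1).
    Rows or columns with a zero margin must be dropped by the caller.
    """
    t = np.asarray(table, dtype=float)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin; drop empty rows/columns first")
    stat, p, df, _ = chi2_contingency(t, correction=False)
    return float(stat), int(df), float(p)


@dataclass
class AssociationResult:
    locus: str
    allele: str
    table: np.ndarray            # carrier/non-carrier (rows) x group (cols)
    groups: tuple[str, str]
    prevalence_pct: dict[str, int]
    p_value: float


def allele_association(
    profiles: Sequence[KoalaProfile],
    outcomes: Mapping[str, str],
    locus: str,
    allele: str,
    groups: tuple[str, str] | None = None,
) -> AssociationResult:
    """Test whether carrying one allele differs between two outcome groups.

    Builds the carrier × outcome 2x2 over the labelled individuals and
    applies the two-sided Fisher exact test; prevalences are reported
    per group rounded to the nearest integer percent.
    """
    by_name = {p.individual: p for p in profiles}
    for ind in outcomes:
        if ind not in by_name:
            raise KeyError(f"no profile for labelled individual {ind!r}")
    observed = set()
    for p in by_name.values():
        calls = p.calls.get(locus, NO_DATA)
        if calls is not NO_DATA:
            observed.update(calls)
    if allele not in observed:
        raise ValueError(f"allele {allele!r} never observed at locus {locus!r}")
    if groups is None:
        labels = sorted(set(outcomes.values()))
        if len(labels) != 2:
            raise ValueError(f"need exactly two outcome groups, got {labels}")
        groups = (labels[0], labels[1])
    table = np.zeros((2, 2), dtype=int)
    for ind, label in outcomes.items():
        if label not in groups:
            continue
        calls = by_name[ind].calls.get(locus, NO_DATA)
        if calls is NO_DATA:
            continue
        col = groups.index(label)
        row = 0 if allele in calls else 1
        table[row, col] += 1
    prevalence = {
        g: round_half_up(100 * table[0, i] / table[:, i].sum())
        if table[:, i].sum()
        else 0
        for i, g in enumerate(groups)
    }
    return AssociationResult(
        locus=locus,
        allele=allele,
        table=table,
        groups=groups,
        prevalence_pct=prevalence,
        p_value=fisher_exact_2x2(table),
    )
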