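"""Distance trees per recombination-free partition.

Neighbour-joining with Jukes–Cantor distances stands in for likelihood tree
inference: it is deterministic, dependency-light, and exact on additive
matrices, which is what per-partition topology comparison needs.  Users
wanting ML trees can feed the partition alignments to an external program.
"""

from __future__ import annotations

import warnings

import numpy as np

from .align import Alignment, p_distance_matrix

#: distance assigned when p >= 0.75 (JC correction undefined: saturation)
SATURATION_CAP = 5.0


def jc_distance(p: float, cap: float = SATURATION_CAP) -> float:
    """Jukes–Cantor distance for a proportion of differing sites."""
    if np.isnan(p):
        return np.nan
    if p >= 0.75:
        return cap
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def jc_distance_matrix(aln: Alignment, cap: float = SATURATION_CAP) -> np.ndarray:
    """Symmetric JC-corrected distance matrix with pairwise deletion."""
    P = p_distance_matrix(aln)
    n = aln.n_seqs
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = jc_distance(P[i, j], cap)
            if np.isnan(d):
                warnings.warn(
                    f"no comparable columns between {aln.names[i]!r} and "
                    f"{aln.names[j]!r}; distance undefined"
                )
            D[i, j] = D[j, i] = d
    return D


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def nj_tree(dist: np.ndarray, names: list[str]) -> str:
    """Neighbour-joining (Saitou–Nei) tree as an unrooted newick string.

    Ties in the Q criterion are broken by the smallest (i, j) index pair in
    the current working order, so output is deterministic.  Negative branch
    lengths are clamped to zero with the deficit moved to the sister branch.
    """
    n = len(names)
    if n == 1:
        return f"{names[0]}:0.000000;"
    if n == 2:
        half = dist[0, 1] / 2.0
        return f"({names[0]}:{_fmt(half)},{names[1]}:{_fmt(half)});"
    D = np.array(dist, dtype=float)
    labels = [f"{nm}" for nm in names]  # newick fragment per active node
    active = list(range(n))
    frags = {i: labels[i] for i in active}
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest (i, j) among minimizers, scanning row-major
        flat = np.argmin(Q)
        qmin = Q.flat[flat]
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        ii, jj = min((int(a), int(b)) for a, b in ties if a < b)
        i, j = active[ii], active[jj]
        dij = sub[ii, jj]
        li = 0.5 * dij + (r[ii] - r[jj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li  # transfer deficit to the sister branch
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
            li = max(li, 0.0)
        new = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for kk in active:
            if kk in (i, j):
                continue
            D[new, kk] = D[kk, new] = 0.5 * (D[i, kk] + D[j, kk] - dij)
        frags[new] = f"({frags[i]}:{_fmt(li)},{frags[j]}:{_fmt(lj)})"
        active = [k for k in active if k not in (i, j)] + [new]
    if len(active) == 3:
        a, b, c = active
        # three-point formulas
        la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
        lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
        lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
        la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
        return (
            f"({frags[a]}:{_fmt(la)},{frags[b]}:{_fmt(lb)},{frags[c]}:{_fmt(lc)});"
        )
    a, b = active  # can only happen for n == 2 handled above, kept defensively
    return f"({frags[a]}:{_fmt(D[a, b] / 2)},{frags[b]}:{_fmt(D[a, b] / 2)});"


def trees_per_partition(
    partitions: list[tuple[tuple[int, int], Alignment]],
    min_sites: int = 100,
) -> tuple[dict[tuple[int, int], str], list[tuple[tuple[int, int], str]]]:
    """NJ tree per partition with at least ``min_sites`` columns.

    Returns (interval -> newick, skip log of (interval, reason)).
    """
    out: dict[tuple[int, int], str] = {}
    skipped: list[tuple[tuple[int, int], str]] = []
    for interval, sub in partitions:
        if sub.length < min_sites:
            skipped.append((interval, f"only {sub.length} columns (< {min_sites})"))
            continue
        D = jc_distance_matrix(sub)
        out[interval] = nj_tree(D, sub.names)
    return out, skipped
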