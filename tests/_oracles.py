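"""Independent brute-force oracles used by the test suite only.

Everything here is deliberately naive: exhaustive topology enumeration with
Fitch parsimony, dynamic-programming interval scheduling, and path-length
matrices from explicitly constructed random trees.  None of it shares code
with the library under test.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# exhaustive Fitch parsimony over all unrooted topologies
# ---------------------------------------------------------------------------


def _rooted_trees(taxa: list[int]):
    """All rooted binary tree shapes (as nested pairs) on the given taxa."""
    if len(taxa) == 1:
        yield taxa[0]
        return
    head, rest = taxa[0], taxa[1:]
    for sub in _rooted_trees(rest):
        yield from _insert_leaf(sub, head)


def _insert_leaf(tree, leaf):
    yield (tree, leaf)
    if isinstance(tree, tuple):
        left, right = tree
        for nl in _insert_leaf(left, leaf):
            yield (nl, right)
        for nr in _insert_leaf(right, leaf):
            yield (left, nr)


def unrooted_topologies(n: int):
    """All unrooted binary topologies on taxa 0..n-1.

    Bijection: unrooted trees on n taxa == rooted trees on n-1 taxa with
    taxon 0 attached at the root.
    """
    if n < 3:
        yield tuple(range(n))
        return
    for sub in _rooted_trees(list(range(1, n))):
        yield (0, sub)


def _fitch(tree, states) -> tuple[frozenset, int]:
    if not isinstance(tree, tuple):
        return frozenset({states[tree]}), 0
    (sl, cl), (sr, cr) = (_fitch(t, states) for t in tree)
    inter = sl & sr
    if inter:
        return inter, cl + cr
    return sl | sr, cl + cr + 1


def fitch_length(tree, column: list[int]) -> int:
    """Parsimony length of one column on one (un)rooted topology."""
    _, cost = _fitch(tree, column)
    return cost


def min_extra_mutations(col_i: list[int], col_j: list[int]) -> int:
    """Minimum extra mutations needed to fit both columns on one tree.

    min over all unrooted topologies of joint parsimony length, minus each
    column's own optimum (number of states - 1).
    """
    n = len(col_i)
    best = None
    for tree in unrooted_topologies(n):
        tot = fitch_length(tree, col_i) + fitch_length(tree, col_j)
        if best is None or tot < best:
            best = tot
    solo = (len(set(col_i)) - 1) + (len(set(col_j)) - 1)
    return best - solo


# ---------------------------------------------------------------------------
# maximum set of disjoint open intervals, by DP (not greedy)
# ---------------------------------------------------------------------------


def max_disjoint_intervals_dp(pairs: list[tuple[int, int]]) -> int:
    """Weighted-interval-scheduling DP; open intervals, endpoints may touch."""
    if not pairs:
        return 0
    ivs = sorted(set(pairs), key=lambda ab: ab[1])
    n = len(ivs)
    f = [0] * (n + 1)
    for k in range(1, n + 1):
        a, b = ivs[k - 1]
        # latest interval ending at or before this one's start
        prev = 0
        for j in range(k - 1, 0, -1):
            if ivs[j - 1][1] <= a:
                prev = j
                break
        f[k] = max(f[k - 1], 1 + f[prev])
    return f[n]


# ---------------------------------------------------------------------------
# random trees with known additive distances
# ---------------------------------------------------------------------------


def random_additive_tree(n: int, rng: np.random.Generator):
    """Random binary topology + branch lengths; returns (newick, D, names).

    D is the exact path-length matrix of the generated tree, computed from
    explicit leaf-to-root paths (no reuse of any library code).
    """
    names = [f"x{i+1}" for i in range(n)]
    # start from a 2-leaf tree, attach each new leaf to a random edge
    # nodes: dict id -> (parent, branch_length); leaves carry names
    parent = {0: None}
    blen = {0: 0.0}
    label = {0: None}
    nxt = 1

    def new_node(par, length, name=None):
        nonlocal nxt
        parent[nxt] = par
        blen[nxt] = length
        label[nxt] = name
        nxt += 1
        return nxt - 1

    a = new_node(0, float(rng.uniform(0.05, 0.3)), names[0])
    b = new_node(0, float(rng.uniform(0.05, 0.3)), names[1])
    edges = [a, b]
    for k in range(2, n):
        target = edges[int(rng.integers(len(edges)))]
        # split target's edge with a new internal node
        mid = new_node(parent[target], blen[target] / 2)
        parent[target] = mid
        blen[target] = blen[target] / 2
        leaf = new_node(mid, float(rng.uniform(0.05, 0.3)), names[k])
        edges.extend([leaf, mid])

    def path_to_root(v):
        out = []
        while v is not None:
            out.append(v)
            v = parent[v]
        return out

    leaves = [v for v in parent if label[v]]
    leaves.sort(key=lambda v: names.index(label[v]))
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi = path_to_root(leaves[i])
            pj = set(path_to_root(leaves[j]))
            d = 0.0
            v = leaves[i]
            while v not in pj:
                d += blen[v]
                v = parent[v]
            lca = v
            u = leaves[j]
            while u != lca:
                d += blen[u]
                u = parent[u]
            D[i, j] = D[j, i] = d

    children: dict[int, list[int]] = {}
    for v, p in parent.items():
        if p is not None:
            children.setdefault(p, []).append(v)

    def newick(v):
        if label[v]:
            return f"{label[v]}:{blen[v]:.6f}"
        inner = ",".join(newick(c) for c in children[v])
        return f"({inner}):{blen[v]:.6f}"

    nwk = f"({','.join(newick(c) for c in children[0])});"
    return nwk, D, names
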