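"""Synthetic alignments with known recombination ground truth.

Clonal data are evolved on a random ultrametric Yule tree under Jukes–Cantor
(multiple hits allowed, optional discrete-gamma rate heterogeneity to mimic
inter-site rate variation).  Mosaic recombinants are produced afterwards by
copying a donor's columns into an acceptor, so the truth table is exact by
construction rather than inferred from an ancestral recombination graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import Alignment, p_distance_matrix
from .errors import InfeasibleError, SizeError

_BASES = "ACGT"


@dataclass(frozen=True)
class TruthEvent:
    acceptor: str
    donor: str
    begin: int  # 0-based half-open
    end: int


@dataclass
class TruthTable:
    events: list[TruthEvent] = field(default_factory=list)
    tree: str = ""
    params: dict = field(default_factory=dict)

    def to_tsv(self) -> str:
        lines = ["acceptor\tdonor\tbegin_1based\tend_1based"]
        for e in self.events:
            lines.append(f"{e.acceptor}\t{e.donor}\t{e.begin + 1}\t{e.end}")
        return "\n".join(lines) + "\n"


@dataclass
class _Node:
    children: list[int]
    branch: float  # length of the edge above this node
    name: str = ""


def _yule_tree(n_taxa: int, rng: np.random.Generator) -> tuple[list[_Node], int]:
    """Grow an ultrametric pure-birth tree; returns (nodes, root index)."""
    nodes = [_Node([], 0.0)]  # root
    root = 0
    active = [root]  # indices of current tips
    depth = {root: 0.0}
    t = 0.0
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / k)
        split = active.pop(int(rng.integers(k)))
        for _ in range(2):
            nodes.append(_Node([], 0.0))
            child = len(nodes) - 1
            nodes[split].children.append(child)
            depth[child] = t
            active.append(child)
        # edge above `split` ends at time t
        nodes[split].branch = 0.0 if split == root else nodes[split].branch
        _set_branch(nodes, depth, split, t)
    total = t + rng.exponential(1.0 / n_taxa)  # extend tips to the present
    for tip in active:
        _set_branch(nodes, depth, tip, total)
    for i, tip in enumerate(sorted(active)):
        nodes[tip].name = f"t{i + 1}"
    return nodes, root


def _set_branch(nodes: list[_Node], depth: dict[int, float], node: int, end_time: float):
    # branch length = own end time minus start time recorded at creation
    nodes[node].branch = end_time - depth[node]
    depth[node] = depth[node]  # start time stays; branch stores duration


def _tip_depth(nodes: list[_Node], root: int) -> float:
    d = 0.0
    node = root
    while nodes[node].children:
        node = nodes[node].children[0]
        d += nodes[node].branch
    return d


def _newick(nodes: list[_Node], node: int) -> str:
    nd = nodes[node]
    if not nd.children:
        return f"{nd.name}:{nd.branch:.6f}"
    inner = ",".join(_newick(nodes, c) for c in nd.children)
    return f"({inner}):{nd.branch:.6f}"


def _evolve(
    nodes: list[_Node],
    root: int,
    length: int,
    rng: np.random.Generator,
    site_rates: np.ndarray,
) -> dict[str, np.ndarray]:
    """Jukes–Cantor simulation down the tree; returns tip name -> codes."""
    root_seq = rng.integers(0, 4, size=length, dtype=np.int8)
    tips: dict[str, np.ndarray] = {}
    stack = [(root, root_seq)]
    while stack:
        node, seq = stack.pop()
        nd = nodes[node]
        if not nd.children:
            tips[nd.name] = seq
            continue
        for child in nd.children:
            t = nodes[child].branch * site_rates
            # JC: P(same) = 1/4 + 3/4 exp(-4t/3); change -> uniform other base
            p_same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
            change = rng.random(length) >= p_same
            child_seq = seq.copy()
            if change.any():
                shift = rng.integers(1, 4, size=int(change.sum()), dtype=np.int8)
                child_seq[change] = (child_seq[change] + shift) % 4
            stack.append((child, child_seq))
    return tips


def simulate_clonal(
    n_taxa: int,
    length: int,
    mean_divergence: float,
    seed: int,
    gamma_shape: float | None = None,
    gamma_categories: int = 4,
) -> tuple[Alignment, str]:
    """Simulate a clonal (recombination-free) alignment.

    mean_divergence is the expected number of substitutions per site on any
    root-to-tip path (the tree is ultrametric, so all paths are equal).
    ``gamma_shape`` switches on discrete-gamma rate heterogeneity across
    sites with that shape parameter and mean rate 1.
    """
    if n_taxa < 2:
        raise SizeError("need >= 2 taxa")
    rng = np.random.default_rng(seed)
    nodes, root = _yule_tree(n_taxa, rng)
    depth = _tip_depth(nodes, root)
    scale = (mean_divergence / depth) if depth > 0 else 0.0
    for nd in nodes:
        nd.branch *= scale
    if gamma_shape is not None:
        # discrete gamma: category means at quantile midpoints, normalized
        from scipy.stats import gamma as _gamma

        qs = (np.arange(gamma_categories) + 0.5) / gamma_categories
        rates = _gamma.ppf(qs, a=gamma_shape, scale=1.0 / gamma_shape)
        rates = rates / rates.mean()
        site_rates = rates[rng.integers(0, gamma_categories, size=length)]
    else:
        site_rates = np.ones(length)
    tips = _evolve(nodes, root, length, rng, site_rates)
    names = sorted(tips, key=lambda s: int(s[1:]))
    rows = ["".join(_BASES[b] for b in tips[n]) for n in names]
    newick = f"({','.join(_newick(nodes, c) for c in nodes[root].children)});"
    return Alignment(names, rows), newick


def implant_events(
    aln: Alignment,
    tree: str,
    n_events: int,
    min_len: int,
    max_len: int,
    min_parent_divergence: float,
    seed: int,
) -> tuple[Alignment, TruthTable]:
    """Copy donor fragments into acceptors, recording exact ground truth.

    Donor/acceptor pairs must be at least ``min_parent_divergence`` apart in
    p-distance; per acceptor, implanted intervals do not overlap.
    """
    rng = np.random.default_rng(seed)
    truth = TruthTable(tree=tree, params={
        "n_taxa": aln.n_seqs, "length": aln.length, "seed": seed,
    })
    if n_events == 0:
        return aln, truth
    pdist = p_distance_matrix(aln)
    eligible = [
        (i, j)
        for i in range(aln.n_seqs)
        for j in range(aln.n_seqs)
        if i != j and pdist[i, j] >= min_parent_divergence
    ]
    if not eligible:
        raise InfeasibleError(
            f"no sequence pair is >= {min_parent_divergence:.3f} divergent"
        )
    rows = [list(r) for r in aln.rows]
    taken: dict[int, list[tuple[int, int]]] = {}
    for _ in range(n_events):
        placed = False
        for _attempt in range(200):
            donor, acceptor = eligible[int(rng.integers(len(eligible)))]
            ln = int(rng.integers(min_len, max_len + 1))
            if ln > aln.length:
                continue
            begin = int(rng.integers(0, aln.length - ln + 1))
            end = begin + ln
            if any(b < end and begin < e for (b, e) in taken.get(acceptor, [])):
                continue
            rows[acceptor][begin:end] = list(aln.rows[donor][begin:end])
            taken.setdefault(acceptor, []).append((begin, end))
            truth.events.append(
                TruthEvent(aln.names[acceptor], aln.names[donor], begin, end)
            )
            placed = True
            break
        if not placed:
            raise InfeasibleError("could not place a non-overlapping event")
    out = Alignment(aln.names, ["".join(r) for r in rows])
    return out, truth
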