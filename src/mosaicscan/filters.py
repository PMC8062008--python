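"""Vetting of recombination signals: PHI, Hudson–Kaplan Rm, misalignment.

The pair score is the exact "refined incompatibility" of two characters:
the minimum number of extra mutations any unrooted tree must spend beyond
the parsimony minimum of each column alone.  For columns i and j with
state counts Vi and Vj, E observed joint states and Cc connected components
of the bipartite state graph, that minimum equals E - (Vi + Vj) + Cc.
A compatible pair scores 0; the classic four-gamete violation scores 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .align import Alignment, parsimony_informative_columns
from .errors import InsufficientDataError
from .scan import RecombinationEvent


@dataclass(frozen=True)
class PhiResult:
    phi: float
    n_pairs: int
    n_informative: int
    p_perm: float
    n_perm: int


@dataclass(frozen=True)
class RmResult:
    rm: int
    incompatible_pairs: list[tuple[int, int]]


@dataclass(frozen=True)
class VetConfig:
    """Knobs of per-event vetting."""

    k_neighbors: int = 5
    pad: int | None = None  # None -> event length
    alpha: float = 0.05
    phi_window: int = 100
    n_perm: int = 1000
    gap_frac: float = 0.3
    gap_run: int = 15
    seed: int = 0


# ---------------------------------------------------------------------------
# pair incompatibility
# ---------------------------------------------------------------------------

def pair_incompatibility(aln: Alignment, i: int, j: int) -> int | None:
    """Minimum extra mutations forced by observing columns *i* and *j* jointly.

    Rows missing at either column are dropped.  Returns ``None`` when either
    column is monomorphic after that removal (the score is undefined).
    """
    codes = aln.codes()
    a, b = codes[:, i], codes[:, j]
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok], b[ok]
    states_a, states_b = set(a.tolist()), set(b.tolist())
    if len(states_a) < 2 or len(states_b) < 2:
        return None
    joint = set(zip(a.tolist(), b.tolist()))
    # connected components of the bipartite state graph via union-find
    nodes = {("a", s) for s in states_a} | {("b", s) for s in states_b}
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (sa, sb) in joint:
        ra, rb = find(("a", sa)), find(("b", sb))
        if ra != rb:
            parent[ra] = rb
    cc = len({find(n) for n in nodes})
    return len(joint) - (len(states_a) + len(states_b)) + cc


def _pair_scores(cx: np.ndarray, cy: np.ndarray) -> np.ndarray:
    """Incompatibility scores for matched column pairs (both (P, n))."""
    P, _ = cx.shape
    valid = (cx >= 0) & (cy >= 0)
    B = np.zeros((P, 4, 4), dtype=bool)
    p_idx, r_idx = np.nonzero(valid)
    B[p_idx, cx[p_idx, r_idx], cy[p_idx, r_idx]] = True
    pres_x = B.any(axis=2)
    pres_y = B.any(axis=1)
    Vx = pres_x.sum(axis=1)
    Vy = pres_y.sum(axis=1)
    E = B.sum(axis=(1, 2))
    M = np.matmul(B.astype(np.uint8), B.transpose(0, 2, 1).astype(np.uint8)) > 0
    eye = np.eye(4, dtype=bool)
    M |= eye & pres_x[:, :, None]
    for _ in range(2):  # 4 nodes: two squarings reach the closure
        M |= np.matmul(M.astype(np.uint8), M.astype(np.uint8)) > 0
    comp_min = np.argmax(M, axis=2)
    cc_x = ((comp_min == np.arange(4)) & pres_x).sum(axis=1)
    score = E - (Vx + Vy) + cc_x
    return np.where((Vx >= 2) & (Vy >= 2), score.astype(float), np.nan)


def incompatibility_matrix(codes_cols: np.ndarray) -> np.ndarray:
    """All-pairs incompatibility scores for a (K, n) column-code matrix.

    Vectorized over pairs; entry is NaN where the score is undefined
    (a column monomorphic after pairwise deletion).  Symmetric, NaN diagonal.
    """
    K, n = codes_cols.shape
    out = np.full((K, K), np.nan)
    if K < 2:
        return out
    iu, ju = np.triu_indices(K, 1)
    score = _pair_scores(codes_cols[iu], codes_cols[ju])
    out[iu, ju] = score
    out[ju, iu] = score
    return out


def _incompatible_pair_straddles(
    codes: np.ndarray, bi_cols: np.ndarray, bp: int, chunk: int = 20000
) -> bool:
    """True if any four-gamete-incompatible biallelic pair straddles ``bp``.

    Only left x right cross pairs are scored, in chunks with early exit.
    """
    left = bi_cols[bi_cols < bp]
    right = bi_cols[bi_cols >= bp]
    if len(left) == 0 or len(right) == 0:
        return False
    li, ri = np.meshgrid(left, right, indexing="ij")
    li, ri = li.ravel(), ri.ravel()
    for s in range(0, len(li), chunk):
        sl = slice(s, s + chunk)
        scores = _pair_scores(codes[:, li[sl]].T, codes[:, ri[sl]].T)
        if np.nanmax(scores, initial=0.0) >= 1:
            return True
    return False


# ---------------------------------------------------------------------------
# PHI
# ---------------------------------------------------------------------------

def phi_test(
    aln: Alignment,
    w: int = 100,
    n_perm: int = 1000,
    seed: int = 0,
) -> PhiResult:
    """Pairwise homoplasy index with a permutation p-value.

    PHI is the mean incompatibility over parsimony-informative site pairs at
    most *w* alignment columns apart.  The null shuffles column contents
    among the informative positions (positions fixed), so recombination —
    which makes *nearby* pairs more compatible than distant ones — pushes
    the observed PHI below the permutation distribution; small ``p_perm``
    is evidence of recombination.
    """
    codes = aln.codes()
    info = parsimony_informative_columns(codes)
    K = len(info)
    if K < 2:
        raise InsufficientDataError("need >= 2 informative sites for PHI")
    pos = info.astype(np.int64)
    iu, ju = np.triu_indices(K, 1)
    near = (pos[ju] - pos[iu]) <= w
    I, J = iu[near], ju[near]
    if len(I) == 0:
        raise InsufficientDataError(f"no informative-site pair within {w} columns")
    S = incompatibility_matrix(codes[:, info].T)
    obs_vals = S[I, J]
    if np.all(np.isnan(obs_vals)):
        raise InsufficientDataError("all eligible pairs have undefined scores")
    phi_obs = float(np.nanmean(obs_vals))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        sigma = rng.permutation(K)
        vals = S[sigma[I], sigma[J]]
        phi_star = np.nanmean(vals) if not np.all(np.isnan(vals)) else np.nan
        if not np.isnan(phi_star) and phi_star <= phi_obs + 1e-12:
            count += 1
    p_perm = (1 + count) / (n_perm + 1)
    return PhiResult(
        phi=phi_obs,
        n_pairs=int(np.sum(~np.isnan(obs_vals))),
        n_informative=K,
        p_perm=p_perm,
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# Hudson–Kaplan Rm
# ---------------------------------------------------------------------------

def _biallelic_columns(codes: np.ndarray) -> np.ndarray:
    counts = np.stack([(codes == s).sum(axis=0) for s in range(4)])
    return np.flatnonzero((counts > 0).sum(axis=0) == 2)


def hudson_kaplan_rm(aln: Alignment) -> RmResult:
    """Hudson–Kaplan lower bound on the number of recombination events.

    Every biallelic column pair showing all four gametes defines an interval
    that must contain a crossover; after discarding intervals that contain
    another, a greedy sweep by right endpoint counts the maximum number of
    pairwise non-overlapping intervals.
    """
    codes = aln.codes()
    bi = _biallelic_columns(codes)
    if len(bi) < 2:
        return RmResult(0, [])
    S = incompatibility_matrix(codes[:, bi].T)
    iu, ju = np.triu_indices(len(bi), 1)
    bad = np.flatnonzero(np.nan_to_num(S[iu, ju], nan=0.0) >= 1)
    pairs = [(int(bi[iu[k]]), int(bi[ju[k]])) for k in bad]
    rm = _max_disjoint_intervals(pairs)
    return RmResult(rm, pairs)


def _max_disjoint_intervals(pairs: list[tuple[int, int]]) -> int:
    """Greedy maximum set of non-overlapping open intervals (i, j)."""
    if not pairs:
        return 0
    # delete intervals that contain another interval: after sorting unique
    # intervals by (start asc, end asc), interval k contains a later one
    # exactly when some later end <= its own end
    uniq = sorted(set(pairs))
    ends = np.array([b for _, b in uniq])
    suffix_min = np.minimum.accumulate(ends[::-1])[::-1]
    kept = []
    for k, (a, b) in enumerate(uniq):
        if k + 1 < len(uniq) and suffix_min[k + 1] <= b:
            continue  # contains a later interval
        if k > 0 and uniq[k - 1][0] == a:
            continue  # same start, larger end: contains the previous one
        kept.append((a, b))
    kept.sort(key=lambda iv: iv[1])
    rm, last_end = 0, -1
    for (a, b) in kept:
        if a >= last_end:  # open intervals: touching endpoints do not overlap
            rm += 1
            last_end = b
    return rm


# ---------------------------------------------------------------------------
# per-event vetting
# ---------------------------------------------------------------------------

def _nearest_neighbors(aln: Alignment, core: list[int], k: int) -> list[int]:
    """Indices of the k rows most similar to any core member (by identity)."""
    codes = aln.codes()
    best = np.full(aln.n_seqs, -np.inf)
    for ci in core:
        a = codes[ci]
        for j in range(aln.n_seqs):
            if j in core:
                continue
            b = codes[j]
            ok = (a >= 0) & (b >= 0)
            n = int(ok.sum())
            ident = (a[ok] == b[ok]).sum() / n if n else 0.0
            best[j] = max(best[j], ident)
    order = [j for j in np.argsort(-best, kind="stable") if j not in core]
    return order[:k]


def vet_event(
    event: RecombinationEvent,
    aln: Alignment,
    cfg: VetConfig | None = None,
) -> RecombinationEvent:
    """Attach false-positive suspicion flags to one detected event.

    phi_suspect: the PHI test on the local neighbourhood sub-alignment fails
    to confirm recombination (p_perm > alpha).  four_gamete_suspect: no
    four-gamete-incompatible site pair straddles either breakpoint.
    misalignment_suspect: the event region is gap-dense or overlaps a long
    mostly-gapped run.
    """
    cfg = cfg or VetConfig()
    begin, end = event.breakpoints
    if not (0 <= begin < end <= aln.length):
        raise ValueError("event coordinates outside alignment")
    flags: set[str] = set(event.flags)
    method = event.method
    core = [
        aln.index(event.recombinant),
        aln.index(event.major_parent),
        aln.index(event.minor_parent),
    ]
    pad = cfg.pad if cfg.pad is not None else (end - begin)
    lo, hi = max(0, begin - pad), min(aln.length, end + pad)
    sub_rows = core + _nearest_neighbors(aln, core, cfg.k_neighbors)
    sub = aln.take_rows(sub_rows).slice_columns(lo, hi)

    # (a) PHI on the local sub-alignment
    if sub.n_seqs < 4:
        method = method + ";phi_untestable"
    else:
        try:
            res = phi_test(sub, w=cfg.phi_window, n_perm=cfg.n_perm, seed=cfg.seed)
            if res.p_perm > cfg.alpha:
                flags.add("phi_suspect")
        except InsufficientDataError:
            method = method + ";phi_untestable"

    # (b) four-gamete support: an incompatible pair must straddle a breakpoint
    sub_codes = sub.codes()
    bi = _biallelic_columns(sub_codes)
    straddles = any(
        _incompatible_pair_straddles(sub_codes, bi, bp - lo)
        for bp in (begin, end)
        if lo < bp < hi
    )
    if not straddles:
        flags.add("four_gamete_suspect")

    # (c) misalignment heuristics on gap structure
    gaps = aln.gap_matrix()
    trip_gaps = gaps[np.ix_(core, range(begin, end))]
    if trip_gaps.mean() > cfg.gap_frac:
        flags.add("misalignment_suspect")
    else:
        col_gapped = gaps.mean(axis=0) >= 0.5
        run = 0
        for col in range(aln.length):
            run = run + 1 if col_gapped[col] else 0
            if run >= cfg.gap_run:
                run_begin = col - run + 1
                if run_begin < end and col + 1 > begin:  # overlap with event
                    flags.add("misalignment_suspect")
                    break
    return replace(event, flags=frozenset(flags), method=method)
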