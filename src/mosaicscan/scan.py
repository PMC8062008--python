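"""Exhaustive triplet scan for recombination signals.

For every triplet (a, b, c) the scan collects *triplet-informative* sites —
columns where exactly two members agree and the third differs, all three
being ungapped and unambiguous — and slides a window over them.  Runs of
windows in which a normally-minority agreement pattern is binomially
over-represented (against the leave-window-out genome-wide proportion of
that pattern) are candidate recombination regions.  Bonferroni correction
controls the family-wise error over triplets and window placements.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import binom

from .align import Alignment
from .errors import SizeError

#: pattern codes: which pair of the triplet agrees at an informative site
PATTERNS = ("ab", "ac", "bc")
_PAIR_OF = {0: (0, 1), 1: (0, 2), 2: (1, 2)}


@dataclass(frozen=True)
class ScanConfig:
    """Tuning parameters of the triplet scan.

    window is counted in triplet-informative sites, not alignment columns,
    so the statistic keeps a constant sample size regardless of divergence.
    """

    window: int = 30
    step: int = 1
    alpha: float = 0.05
    min_event_len: int = 3
    bonferroni_factor_mode: str = "triplets_x_windows"
    max_missing_frac: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not (self.window >= self.min_event_len >= 1):
            raise ValueError("require window >= min_event_len >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("require 0 < alpha < 1")
        if self.bonferroni_factor_mode not in ("triplets_x_windows", "triplets_only"):
            raise ValueError(f"unknown mode {self.bonferroni_factor_mode!r}")


@dataclass(frozen=True)
class TripletProfile:
    triplet: tuple[int, int, int]
    informative_positions: np.ndarray  # strictly increasing alignment columns
    support_pattern: np.ndarray  # int8 codes into PATTERNS, same length

    @property
    def n_informative(self) -> int:
        return len(self.informative_positions)


@dataclass(frozen=True)
class CandidateRegion:
    """A significant run, in informative-site index space of its profile."""

    pattern: int  # code into PATTERNS
    first_idx: int  # first informative site of the trimmed run (inclusive)
    last_idx: int  # last informative site of the trimmed run (inclusive)
    p_raw: float
    n_support: int  # informative sites in the run carrying the pattern


@dataclass(frozen=True)
class RecombinationEvent:
    recombinant: str
    major_parent: str
    minor_parent: str
    breakpoints: tuple[int, int]  # half-open alignment columns
    p_raw: float
    p_corrected: float
    flags: frozenset[str] = frozenset()
    method: str = "triplet"

    def __post_init__(self):
        b, e = self.breakpoints
        assert b < e, "empty breakpoint interval"
        assert self.p_corrected >= self.p_raw


def binomial_tail(m: int | np.ndarray, n: int, p: float | np.ndarray) -> float | np.ndarray:
    """P(X >= m) for X ~ Binomial(n, p)."""
    return binom.sf(np.asarray(m) - 1, n, p)


def build_triplet_profile(aln: Alignment, a: int, b: int, c: int) -> TripletProfile:
    """Collect the informative sites of one triplet.

    A column is informative when all three rows are unambiguous nucleotides
    and the states split exactly 2-vs-1; three-way identical or three-way
    distinct columns carry no pattern.
    """
    if aln.n_seqs < 3:
        raise SizeError("triplet profile needs an alignment of >= 3 sequences")
    if len({a, b, c}) != 3:
        raise ValueError("triplet indices must be distinct")
    codes = aln.codes()
    ra, rb, rc = codes[a], codes[b], codes[c]
    valid = (ra >= 0) & (rb >= 0) & (rc >= 0)
    eq_ab, eq_ac, eq_bc = ra == rb, ra == rc, rb == rc
    n_eq = eq_ab.astype(np.int8) + eq_ac + eq_bc
    informative = valid & (n_eq == 1)
    pos = np.flatnonzero(informative)
    pat = np.where(eq_ab[pos], 0, np.where(eq_ac[pos], 1, 2)).astype(np.int8)
    return TripletProfile((a, b, c), pos, pat)


def _window_starts(n_sites: int, cfg: ScanConfig) -> np.ndarray:
    return np.arange(0, n_sites - cfg.window + 1, cfg.step)


def n_windows(n_sites: int, cfg: ScanConfig) -> int:
    return len(_window_starts(n_sites, cfg)) if n_sites >= cfg.window else 0


# exact binomial tails are only evaluated where this normal z-score bound
# says the window could possibly reach the corrected threshold
_Z_PREFILTER = 2.5


def scan_triplet(
    profile: TripletProfile,
    cfg: ScanConfig,
    bonferroni_factor: float,
    background: np.ndarray | None = None,
) -> list[CandidateRegion]:
    """Scan one triplet profile for pattern-clustered windows.

    ``background`` may supply genome-wide per-pattern counts (defaults to the
    profile's own counts); the per-window null proportion excludes the
    current window from those counts.
    """
    K = profile.n_informative
    w = cfg.window
    if K < w:
        return []
    pat = profile.support_pattern
    starts = _window_starts(K, cfg)
    onehot = np.zeros((3, K), dtype=np.int32)
    onehot[pat, np.arange(K)] = 1
    csum = np.concatenate([np.zeros((3, 1), np.int32), np.cumsum(onehot, axis=1)], axis=1)
    win_counts = csum[:, starts + w] - csum[:, starts]  # (3, n_windows)
    totals = (
        background.astype(np.int64)
        if background is not None
        else csum[:, -1].astype(np.int64)
    )
    total_all = int(totals.sum())

    regions: list[CandidateRegion] = []
    out_n = total_all - w
    if out_n <= 0:
        return []
    for q in range(3):
        m = win_counts[q]
        out_cnt = totals[q] - m
        p_hat = out_cnt / out_n
        # keep the null proportion off the degenerate boundary
        p_hat = np.clip(p_hat, 0.5 / out_n, 1 - 0.5 / out_n)
        mu = w * p_hat
        sd = np.sqrt(w * p_hat * (1 - p_hat))
        rough = (m - mu) / np.maximum(sd, 1e-12)
        cand = np.flatnonzero((rough >= _Z_PREFILTER) & (m > 0))
        if len(cand) == 0:
            continue
        p_raw = np.ones(len(starts))
        p_raw[cand] = binomial_tail(m[cand], w, p_hat[cand])
        sig = np.flatnonzero(p_raw * bonferroni_factor < cfg.alpha)
        if len(sig) == 0:
            continue
        # merge overlapping significant windows into maximal runs
        runs: list[list[int]] = []
        for s_idx in sig:
            st = starts[s_idx]
            if runs and st <= runs[-1][1]:  # overlaps previous run's span
                runs[-1][1] = max(runs[-1][1], st + w - 1)
                runs[-1][2] = min(runs[-1][2], p_raw[s_idx])
            else:
                runs.append([st, st + w - 1, p_raw[s_idx]])
        seen: set[tuple[int, int]] = set()
        for st, en, p_best in runs:
            st, en = _refine_run(pat, q, st, en, w)
            inside = np.flatnonzero(pat[st : en + 1] == q) + st
            if len(inside) < cfg.min_event_len:
                continue
            key = (int(inside[0]), int(inside[-1]))
            if key in seen:  # two seeds refined to the same segment
                continue
            seen.add(key)
            regions.append(
                CandidateRegion(
                    pattern=q,
                    first_idx=key[0],
                    last_idx=key[1],
                    p_raw=float(p_best),
                    n_support=int(len(inside)),
                )
            )
    if not regions:
        return []
    # Second pass: a strong region distorts the genome-wide pattern
    # proportions (its own pattern is inflated, the others deflated), which
    # can make perfectly ordinary stretches elsewhere look enriched.
    # Re-test every candidate against a background restricted to sites
    # outside ALL first-pass regions and keep only the survivors.
    in_region = np.zeros(K, dtype=bool)
    for r in regions:
        in_region[r.first_idx : r.last_idx + 1] = True
    out_sites = int((~in_region).sum())
    if out_sites <= 0:
        return regions
    survivors: list[CandidateRegion] = []
    for r in regions:
        q = r.pattern
        out_q = int(((pat == q) & ~in_region).sum())
        p_clean = min(max(out_q / out_sites, 0.5 / out_sites), 1 - 0.5 / out_sites)
        lo = max(0, r.first_idx - w + 1)
        hi = min(r.last_idx, K - w)
        if hi < lo:
            continue
        span = slice(
            int(np.searchsorted(starts, lo)),
            int(np.searchsorted(starts, hi, side="right")),
        )
        if span.start >= span.stop:
            continue
        p_min = float(np.min(binomial_tail(win_counts[q][span], w, p_clean)))
        if p_min * bonferroni_factor < cfg.alpha:
            survivors.append(
                CandidateRegion(
                    pattern=q,
                    first_idx=r.first_idx,
                    last_idx=r.last_idx,
                    p_raw=p_min,
                    n_support=r.n_support,
                )
            )
    return survivors


def _refine_run(pat: np.ndarray, q: int, st: int, en: int, w: int) -> tuple[int, int]:
    """Sharpen a merged window run to the locally maximal pattern cluster.

    A raw run spans whole windows and so drags in up to a window's worth of
    background sites on either flank.  Within the run padded by one window,
    sites are scored log(p1/p0) when they carry the candidate pattern and
    log((1-p1)/(1-p0)) otherwise (p1 = in-run pattern fraction, p0 = the
    leave-run-out background fraction) and the maximum-scoring contiguous
    segment replaces the run.  Falls back to the raw run if the best
    segment misses it entirely.
    """
    K = len(pat)
    lo, hi = max(0, st - w), min(K - 1, en + w)
    is_q = pat[lo : hi + 1] == q
    m_run = int((pat[st : en + 1] == q).sum())
    run_len = en - st + 1
    out_len = K - run_len
    out_q = int((pat == q).sum()) - m_run
    p0 = out_q / out_len if out_len else 0.0
    p0 = min(max(p0, 1e-3), 0.999)
    p1 = min(max(m_run / run_len, p0 + 1e-3), 0.999)
    s_hit = np.log(p1 / p0)
    s_miss = np.log((1 - p1) / (1 - p0))
    scores = np.where(is_q, s_hit, s_miss)
    # Kadane with segment tracking
    best, cur = -np.inf, 0.0
    b_lo = b_hi = c_lo = 0
    for k, sc in enumerate(scores):
        if cur <= 0:
            cur, c_lo = sc, k
        else:
            cur += sc
        if cur > best:
            best, b_lo, b_hi = cur, c_lo, k
    seg_lo, seg_hi = lo + b_lo, lo + b_hi
    if seg_hi < st or seg_lo > en:  # refinement lost the seed; keep raw run
        return st, en
    return seg_lo, seg_hi


def region_background_pattern(region: CandidateRegion, profile: TripletProfile) -> int:
    """Plurality pattern among informative sites outside the region.

    This is the clonal signal the region interrupts.  Falls back to the
    commonest non-region pattern code if the region pattern itself is still
    the outside plurality (possible for very short alignments).
    """
    pat = profile.support_pattern
    outside = np.concatenate([pat[: region.first_idx], pat[region.last_idx + 1 :]])
    counts = np.bincount(outside, minlength=3).astype(float)
    order = np.argsort(-counts, kind="stable")
    for code in order:
        if int(code) != region.pattern:
            best_other = int(code)
            break
    return int(order[0]) if int(order[0]) != region.pattern else best_other


def demarcate_breakpoints(
    region: CandidateRegion,
    profile: TripletProfile,
    aln_len: int,
    bg_pattern: int | None = None,
) -> tuple[int, int]:
    """Place breakpoints midway between the region and its clonal flanks.

    The left breakpoint is the floor midpoint between the last informative
    site before the region that supports the background (plurality) pattern
    and the first in-region site; the right side mirrors this.  Without a
    flanking background site the alignment terminus is used.
    """
    if bg_pattern is None:
        bg_pattern = region_background_pattern(region, profile)
    pos = profile.informative_positions
    pat = profile.support_pattern
    first_col = int(pos[region.first_idx])
    last_col = int(pos[region.last_idx])

    left_bg = np.flatnonzero(pat[: region.first_idx] == bg_pattern)
    if len(left_bg):
        begin = (int(pos[left_bg[-1]]) + first_col) // 2
    else:
        begin = 0
    right_bg = np.flatnonzero(pat[region.last_idx + 1 :] == bg_pattern)
    if len(right_bg):
        right_col = int(pos[region.last_idx + 1 + right_bg[0]])
        end = (last_col + right_col) // 2
    else:
        end = aln_len
    end = max(end, begin + 1)  # guarantee a non-empty interval
    return begin, end


def _event_from_region(
    region: CandidateRegion,
    profile: TripletProfile,
    aln: Alignment,
    cfg: ScanConfig,
    bonferroni_factor: float,
    bg_pattern: int | None = None,
) -> RecombinationEvent:
    a, b, c = profile.triplet
    members = (a, b, c)
    if bg_pattern is None:
        bg_pattern = region_background_pattern(region, profile)
    q_pair = set(_PAIR_OF[region.pattern])
    bg_pair = set(_PAIR_OF[bg_pattern])
    shared = q_pair & bg_pair
    method = "triplet"
    if len(shared) == 1:
        rec_local = shared.pop()
        minor_local = (q_pair - {rec_local}).pop()
        major_local = (bg_pair - {rec_local}).pop()
    else:  # defensive: cannot occur with three members, kept per contract
        rec_local = (set(range(3)) - bg_pair).pop()
        minor_local = (q_pair - {rec_local}).pop() if q_pair - {rec_local} else rec_local
        major_local = (bg_pair - {rec_local}).pop()
        method = "triplet;ambiguous_recombinant"
    begin, end = demarcate_breakpoints(region, profile, aln.length, bg_pattern)
    p_corr = min(1.0, region.p_raw * bonferroni_factor)
    return RecombinationEvent(
        recombinant=aln.names[members[rec_local]],
        major_parent=aln.names[members[major_local]],
        minor_parent=aln.names[members[minor_local]],
        breakpoints=(begin, end),
        p_raw=region.p_raw,
        p_corrected=p_corr,
        method=method,
    )


# ---------------------------------------------------------------------------
# consolidation across triplets
# ---------------------------------------------------------------------------

def _reciprocal_overlap(e1: RecombinationEvent, e2: RecombinationEvent) -> bool:
    # overlap is judged against the smaller interval so that a fragmentary
    # report nested inside a full-length one still counts as the same event
    b1, n1 = e1.breakpoints, e1.breakpoints[1] - e1.breakpoints[0]
    b2, n2 = e2.breakpoints, e2.breakpoints[1] - e2.breakpoints[0]
    ov = min(b1[1], b2[1]) - max(b1[0], b2[0])
    return ov > 0 and ov / min(n1, n2) >= 0.5


def _union_groups(
    events: list[RecombinationEvent], idx_sets: list[list[int]]
) -> dict[int, list[int]]:
    """Union-find over reciprocal overlap, restricted to each index set."""
    parent = list(range(len(events)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for idxs in idx_sets:
        for i, j in combinations(idxs, 2):
            if _reciprocal_overlap(events[i], events[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[int]] = {}
    for i in range(len(events)):
        groups.setdefault(find(i), []).append(i)
    return groups


def _exemplar(events: list[RecombinationEvent], idxs: list[int]) -> RecombinationEvent:
    best = min(
        idxs,
        key=lambda i: (
            events[i].p_corrected,
            events[i].breakpoints[0],
            events[i].recombinant,
        ),
    )
    return events[best]


def consolidate_events(events: list[RecombinationEvent]) -> list[RecombinationEvent]:
    """Collapse multiply-reported signals of one event into one exemplar.

    Stage 1 groups same-recombinant events with >= 50% overlap of the
    smaller interval (union-find); the exemplar of a group is the
    minimum-p member, ties broken by smaller begin then recombinant name.
    Stage 2 collapses overlapping exemplars that *disagree* on the
    recombinant's name: a triplet sees only which member switches partners,
    so one physical event surfaces under several names (the acceptor, the
    donor, or a relative of either).  Each overlap group is reduced to its
    minimum-p exemplar; naming is settled afterwards by
    ``resolve_donor_acceptor``, which works on the breakpoint interval and
    is independent of which triplet reported it.
    """
    if not events:
        return []
    by_rec: dict[str, list[int]] = {}
    for i, e in enumerate(events):
        by_rec.setdefault(e.recombinant, []).append(i)
    stage1 = [
        _exemplar(events, idxs)
        for idxs in _union_groups(events, list(by_rec.values())).values()
    ]
    # stage 2: overlap groups across recombinant names
    groups = _union_groups(stage1, [list(range(len(stage1)))])
    out = [_exemplar(stage1, idxs) for idxs in groups.values()]
    out.sort(key=lambda e: (e.breakpoints[0], e.breakpoints[1], e.recombinant))
    return out


def _affinity_shift(codes: np.ndarray, x: int, others: list[int],
                    begin: int, end: int) -> float:
    """Mean |identity change| of row x toward others, inside vs outside."""
    shifts = []
    inside = np.zeros(codes.shape[1], dtype=bool)
    inside[begin:end] = True
    for z in others:
        ok = (codes[x] >= 0) & (codes[z] >= 0)
        same = codes[x] == codes[z]
        n_in = int((ok & inside).sum())
        n_out = int((ok & ~inside).sum())
        if n_in == 0 or n_out == 0:
            continue
        ident_in = float((same & ok & inside).sum() / n_in)
        ident_out = float((same & ok & ~inside).sum() / n_out)
        shifts.append(abs(ident_in - ident_out))
    return float(np.mean(shifts)) if shifts else 0.0


def resolve_donor_acceptor(
    events: list[RecombinationEvent], aln: Alignment
) -> list[RecombinationEvent]:
    """Decide which of the two inside-region partners is the recombinant.

    Inside the transferred region the recombinant and its minor parent are
    near-identical, so a triplet signal alone cannot tell acceptor from
    donor.  The acceptor is the one whose identity profile against the rest
    of the alignment shifts across the region boundary (it temporarily joins
    the donor's neighbourhood); the donor's profile barely moves.  When the
    minor parent shifts more than the named recombinant the two are swapped
    and the major parent is re-anchored to the new recombinant's closest
    outside partner.
    """
    codes = aln.codes()
    out: list[RecombinationEvent] = []
    for e in events:
        r, m = aln.index(e.recombinant), aln.index(e.minor_parent)
        begin, end = e.breakpoints
        others = [i for i in range(aln.n_seqs) if i not in (r, m)]
        if not others:
            out.append(e)
            continue
        if _affinity_shift(codes, m, others, begin, end) > _affinity_shift(
            codes, r, others, begin, end
        ):
            outside = np.ones(aln.length, dtype=bool)
            outside[begin:end] = False
            best, best_ident = e.major_parent, -1.0
            for z in others:
                ok = (codes[m] >= 0) & (codes[z] >= 0) & outside
                n = int(ok.sum())
                if n == 0:
                    continue
                ident = float(((codes[m] == codes[z]) & ok).sum() / n)
                if ident > best_ident:
                    best, best_ident = aln.names[z], ident
            out.append(
                RecombinationEvent(
                    recombinant=e.minor_parent,
                    major_parent=best,
                    minor_parent=e.recombinant,
                    breakpoints=e.breakpoints,
                    p_raw=e.p_raw,
                    p_corrected=e.p_corrected,
                    flags=e.flags,
                    method=e.method,
                )
            )
        else:
            out.append(e)
    return out


def scan_all(
    aln: Alignment,
    cfg: ScanConfig | None = None,
    triplets: list[tuple[int, int, int]] | None = None,
    admissible_recombinants: set[str] | None = None,
) -> list[RecombinationEvent]:
    """Scan every triplet (or a provided subset) and consolidate events.

    ``admissible_recombinants`` restricts reported events to named
    recombinants (used by the query-vs-reference mode).
    """
    cfg = cfg or ScanConfig()
    n = aln.n_seqs
    if n < 3:
        raise SizeError("recombination scan needs >= 3 sequences")
    trips = triplets if triplets is not None else list(combinations(range(n), 3))
    n_triplets = len(trips)
    raw_events: list[RecombinationEvent] = []
    for (a, b, c) in trips:
        profile = build_triplet_profile(aln, a, b, c)
        nw = n_windows(profile.n_informative, cfg)
        if nw == 0:
            continue
        if cfg.bonferroni_factor_mode == "triplets_x_windows":
            factor = float(n_triplets) * nw
        else:
            factor = float(n_triplets)
        for region in scan_triplet(profile, cfg, factor):
            raw_events.append(_event_from_region(region, profile, aln, cfg, factor))
    events = consolidate_events(raw_events)
    events = resolve_donor_acceptor(events, aln)
    events = consolidate_events(events)  # swaps may unify names
    if admissible_recombinants is not None:
        events = [e for e in events if e.recombinant in admissible_recombinants]
    return events


def bonferroni_factor_for(aln: Alignment, cfg: ScanConfig, n_informative: int) -> float:
    """Worked factor for one triplet: C(n,3) x window placements."""
    base = comb(aln.n_seqs, 3)
    if cfg.bonferroni_factor_mode == "triplets_only":
        return float(base)
    return float(base) * n_windows(n_informative, cfg)


def events_to_frame(events: list[RecombinationEvent]) -> pd.DataFrame:
    """Event table with 1-based inclusive coordinates for reporting."""
    rows = [
        {
            "recombinant": e.recombinant,
            "major_parent": e.major_parent,
            "minor_parent": e.minor_parent,
            "begin_1based": e.breakpoints[0] + 1,
            "end_1based": e.breakpoints[1],
            "p_raw": e.p_raw,
            "p_corrected": e.p_corrected,
            "flags": ";".join(sorted(e.flags)),
            "method": e.method,
        }
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "recombinant",
            "major_parent",
            "minor_parent",
            "begin_1based",
            "end_1based",
            "p_raw",
            "p_corrected",
            "flags",
            "method",
        ],
    )
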