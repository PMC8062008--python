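"""Breakpoint-distribution tests against genome annotation.

The null places breakpoints independently and uniformly over alignment
columns; per-label deviations from the expected count are judged by a
two-tailed permutation p-value (distance from the null mean), with
Benjamini–Hochberg adjustment across labels of a scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .annotation import AnnotationTrack
from .errors import InsufficientDataError
from .scan import RecombinationEvent

SCHEMES = ("coding_vs_noncoding", "per_gene", "edge_vs_interior")


@dataclass
class BreakpointSet:
    positions: list[int]
    source_events: list[RecombinationEvent] = field(default_factory=list)

    @classmethod
    def from_events(
        cls,
        events: list[RecombinationEvent],
        aln_len: int,
        collapse_per_event: bool = False,
    ) -> "BreakpointSet":
        """Both breakpoints per event, dropping terminus-truncated ones.

        With ``collapse_per_event`` each event contributes at most one
        position (its midpoint), for robustness against double counting.
        """
        pos: list[int] = []
        for e in events:
            b, en = e.breakpoints
            inner = [p for p in (b, en) if 0 < p < aln_len]
            if collapse_per_event:
                if inner:
                    pos.append((b + en) // 2)
            else:
                pos.extend(inner)
        return cls(sorted(pos), list(events))


@dataclass
class RegionPartition:
    scheme: str
    labels: np.ndarray  # one string label per column
    notes: list[str] = field(default_factory=list)


def partition_columns(
    annotation: AnnotationTrack,
    aln_len: int,
    scheme: str,
    edge_frac: float = 0.1,
) -> RegionPartition:
    """Label every alignment column under one annotation scheme."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    annotation.validate(aln_len)
    notes: list[str] = []
    if scheme == "coding_vs_noncoding":
        labels = np.array(["noncoding"] * aln_len, dtype=object)
        for f in annotation.of_type("CDS"):
            for (s, e) in f.intervals:
                labels[s:e] = "coding"
        return RegionPartition(scheme, labels, notes)

    genes = annotation.of_type("gene") or annotation.of_type("CDS")
    labels = np.array(["intergenic"] * aln_len, dtype=object)
    # nearest-start wins on overlap; ties by lexicographic id
    claimants: dict[int, list[tuple[int, str]]] = {}
    for f in sorted(genes, key=lambda g: g.feature_id):
        start = f.span[0]
        for (s, e) in f.intervals:
            for c in range(s, e):
                claimants.setdefault(c, []).append((abs(c - start), f.feature_id))
    owner = {
        c: min(cands)[1] for c, cands in claimants.items()
    }
    if any(len({fid for _, fid in cands}) > 1 for cands in claimants.values()):
        notes.append("overlapping genes: columns assigned to nearest gene start")

    if scheme == "per_gene":
        for c, fid in owner.items():
            labels[c] = fid
        return RegionPartition(scheme, labels, notes)

    # edge_vs_interior
    by_gene: dict[str, list[int]] = {}
    for c, fid in sorted(owner.items()):
        by_gene.setdefault(fid, []).append(c)
    for fid, cols in by_gene.items():
        k = ceil(edge_frac * len(cols))
        for c in cols:
            labels[c] = "interior"
        for c in cols[:k] + cols[-k:] if k else []:
            labels[c] = "edge"
    return RegionPartition(scheme, labels, notes)


def breakpoint_region_test(
    bps: BreakpointSet,
    part: RegionPartition,
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation test of breakpoint counts per region label.

    Null: each breakpoint lands uniformly on any column.  Two-tailed p per
    label from |count - expected|; BH-adjusted across labels.
    """
    if not bps.positions:
        raise InsufficientDataError("no breakpoints to test")
    L = len(part.labels)
    uniq = sorted(set(part.labels.tolist()))
    code = {lab: k for k, lab in enumerate(uniq)}
    col_code = np.array([code[lab] for lab in part.labels], dtype=np.int64)
    n_lab = len(uniq)
    n_bp = len(bps.positions)
    observed = np.bincount(col_code[np.array(bps.positions)], minlength=n_lab)
    span = np.bincount(col_code, minlength=n_lab)
    expected = n_bp * span / L
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, L, size=(n_perm, n_bp))
    lab_draws = col_code[draws]  # (n_perm, n_bp)
    offset = np.arange(n_perm)[:, None] * n_lab
    perm_counts = np.bincount(
        (lab_draws + offset).ravel(), minlength=n_perm * n_lab
    ).reshape(n_perm, n_lab)
    rows = []
    for k, lab in enumerate(uniq):
        if span[k] == 0:
            continue
        obs_dev = abs(observed[k] - expected[k])
        extreme = np.abs(perm_counts[:, k] - expected[k]) >= obs_dev - 1e-9
        p = (1 + int(extreme.sum())) / (n_perm + 1)
        rows.append(
            {
                "scheme": part.scheme,
                "label": lab,
                "span_columns": int(span[k]),
                "observed": int(observed[k]),
                "expected_mean": float(expected[k]),
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    df["p_BH"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df


def breakpoint_density(
    bps: BreakpointSet,
    aln_len: int,
    window: int = 200,
    step: int = 50,
) -> pd.DataFrame:
    """Sliding-window breakpoint counts (centers reported 1-based)."""
    if not (window >= step >= 1):
        raise ValueError("require window >= step >= 1")
    pos = np.array(bps.positions, dtype=np.int64)
    starts = list(range(0, max(aln_len - window, 0) + 1, step))
    if not starts:
        starts = [0]
    last_full = starts[-1]
    if last_full + window < aln_len:
        starts.append(last_full + step)
    rows = []
    for s in starts:
        e = min(s + window, aln_len)
        count = int(((pos >= s) & (pos < e)).sum())
        rows.append(
            {
                "center_1based": (s + e) // 2 + 1,
                "begin_1based": s + 1,
                "end_1based": e,
                "count": count,
                "partial": e - s < window,
            }
        )
    return pd.DataFrame(rows)
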