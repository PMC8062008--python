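"""Recombination-free dataset construction.

Four output modes: drop recombinant sequences, mask transferred fragments,
split recombinants into backbone + per-event parts, or cut the alignment at
breakpoints into sub-region alignments.  Plus annotation-aware, codon-clean
gene alignment extraction.
"""

from __future__ import annotations

import warnings

import numpy as np

from .align import ALLOWED_CHARS, Alignment, reverse_complement
from .annotation import AnnotationTrack
from .errors import ConfigError, SizeError
from .scan import RecombinationEvent


def _effective_events(
    events: list[RecombinationEvent], include_flagged: bool
) -> list[RecombinationEvent]:
    if include_flagged:
        return list(events)
    return [e for e in events if not e.flags]


def strip_recombinants(
    aln: Alignment,
    events: list[RecombinationEvent],
    include_flagged: bool = False,
) -> Alignment:
    """Remove every sequence named recombinant in >= 1 (unflagged) event."""
    drop = {e.recombinant for e in _effective_events(events, include_flagged)}
    unknown = drop - set(aln.names)
    if unknown:
        raise ConfigError(f"recombinant(s) not in alignment: {sorted(unknown)}")
    keep = [i for i, n in enumerate(aln.names) if n not in drop]
    if len(keep) < 2:
        raise SizeError(
            f"removing {len(drop)} recombinants would leave {len(keep)} sequences"
        )
    return aln.take_rows(keep)


def mask_recombinant_fragments(
    aln: Alignment,
    events: list[RecombinationEvent],
    missing_char: str = "N",
    include_flagged: bool = False,
) -> Alignment:
    """Replace each event's columns in its recombinant row by missing data.

    Overlapping events union their masks; other rows are untouched.
    """
    if missing_char not in ALLOWED_CHARS or len(missing_char) != 1:
        raise ConfigError(f"invalid missing character {missing_char!r}")
    rows = [list(r) for r in aln.rows]
    for e in _effective_events(events, include_flagged):
        i = aln.index(e.recombinant)
        b, en = e.breakpoints
        rows[i][b:en] = missing_char * (en - b)
    return Alignment(aln.names, ["".join(r) for r in rows])


def split_recombinants(
    aln: Alignment,
    events: list[RecombinationEvent],
    missing_char: str = "N",
    include_flagged: bool = False,
) -> Alignment:
    """Split each recombinant into a backbone row plus one row per event.

    The backbone carries the sequence outside all events (event regions
    masked); each part row carries exactly one event's columns.  Together
    they partition the original row's non-missing content.
    """
    if missing_char not in ALLOWED_CHARS or len(missing_char) != 1:
        raise ConfigError(f"invalid missing character {missing_char!r}")
    eff = _effective_events(events, include_flagged)
    by_rec: dict[str, list[RecombinationEvent]] = {}
    for e in eff:
        by_rec.setdefault(e.recombinant, []).append(e)
    existing = set(aln.names)
    names: list[str] = []
    rows: list[str] = []

    def _unique(name: str) -> str:
        if name not in existing and name not in names:
            return name
        i = 1
        while f"{name}_r{i}" in existing or f"{name}_r{i}" in names:
            i += 1
        warnings.warn(f"name collision: using {name}_r{i} for {name}")
        return f"{name}_r{i}"

    L = aln.length
    for name, row in zip(aln.names, aln.rows):
        evs = by_rec.get(name)
        if not evs:
            names.append(name)
            rows.append(row)
            continue
        evs = sorted(evs, key=lambda e: e.breakpoints)
        backbone = list(row)
        claimed = np.zeros(L, dtype=bool)  # overlap columns go to one part only
        parts: list[list[str]] = []
        for e in evs:
            b, en = e.breakpoints
            backbone[b:en] = missing_char * (en - b)
            part = [missing_char] * L
            for c in range(b, en):
                if not claimed[c]:
                    part[c] = row[c]
                    claimed[c] = True
            parts.append(part)
        names.append(_unique(f"{name}_bb"))
        rows.append("".join(backbone))
        for k, part in enumerate(parts, 1):
            names.append(_unique(f"{name}_ev{k}"))
            rows.append("".join(part))
    return Alignment(names, rows)


def partition_alignment(
    aln: Alignment,
    events_or_breakpoints: list[RecombinationEvent] | list[int],
) -> tuple[list[tuple[tuple[int, int], Alignment]], list[dict]]:
    """Cut the alignment at breakpoint columns into sub-region alignments.

    Returns (list of ((begin, end), sub-alignment), partition table rows
    with 1-based inclusive coordinates).  Breakpoints at a terminus create
    no split and are dropped with a note.
    """
    bps: set[int] = set()
    for item in events_or_breakpoints:
        if isinstance(item, RecombinationEvent):
            bps.update(item.breakpoints)
        else:
            bps.add(int(item))
    dropped = sorted(b for b in bps if b <= 0 or b >= aln.length)
    cuts = sorted(b for b in bps if 0 < b < aln.length)
    bounds = [0] + cuts + [aln.length]
    parts: list[tuple[tuple[int, int], Alignment]] = []
    table: list[dict] = []
    for k, (b, e) in enumerate(zip(bounds[:-1], bounds[1:]), 1):
        sub = aln.slice_columns(b, e)
        parts.append(((b, e), sub))
        table.append(
            {"partition_id": k, "begin_1based": b + 1, "end_1based": e}
        )
    if dropped:
        table.append(
            {"partition_id": "note", "begin_1based": "",
             "end_1based": f"dropped terminus breakpoints: {dropped}"}
        )
    return parts, table


# ---------------------------------------------------------------------------
# gene extraction
# ---------------------------------------------------------------------------

def _overlap_frame_columns(annotation: AnnotationTrack) -> set[int]:
    """Columns covered by >= 2 CDS features in different reading frames."""
    frames: dict[int, set[tuple[str, int]]] = {}
    for f in annotation.of_type("CDS"):
        offset = 0
        for k, (s, e) in enumerate(f.intervals):
            ph = f.phase[k] if f.phase else 0
            cols = range(s, e) if f.strand == "+" else range(e - 1, s - 1, -1)
            for pos_in_cds, col in enumerate(cols, start=offset):
                frames.setdefault(col, set()).add(
                    (f.feature_id, (pos_in_cds - ph) % 3)
                )
            offset += e - s
    out = set()
    for col, fs in frames.items():
        if len({fr for _, fr in fs}) >= 2 and len({fid for fid, _ in fs}) >= 2:
            out.add(col)
    return out


def extract_gene_alignments(
    aln: Alignment,
    annotation: AnnotationTrack,
    drop_partial_codons: bool = True,
    exclude_overlap_frames: bool = False,
) -> dict[str, Alignment]:
    """Spliced, strand-corrected, optionally codon-clean gene alignments.

    Per CDS feature: intervals are concatenated in transcription order,
    minus-strand genes are reverse-complemented, the initial phase is
    trimmed, and (by default) trailing partial codons and codons containing
    frame-shifting gaps are removed column-synchronously so the output stays
    aligned and a multiple of three long.
    """
    annotation.validate(aln.length)
    cds = annotation.of_type("CDS")
    if not cds:
        warnings.warn("no CDS features: nothing to extract")
        return {}
    excluded = _overlap_frame_columns(annotation) if exclude_overlap_frames else set()
    out: dict[str, Alignment] = {}
    for f in cds:
        pieces: list[list[str]] = [[] for _ in aln.rows]
        for (s, e) in f.intervals:
            cols = [c for c in range(s, e) if c not in excluded]
            for ri, row in enumerate(aln.rows):
                chunk = "".join(row[c] for c in cols)
                if f.strand == "-":
                    chunk = reverse_complement(chunk)
                pieces[ri].append(chunk)
        rows = ["".join(p) for p in pieces]
        ph = f.phase[0] if f.phase else 0
        if ph:
            rows = [r[ph:] for r in rows]
        if drop_partial_codons and rows and rows[0]:
            L = len(rows[0]) - (len(rows[0]) % 3)
            rows = [r[:L] for r in rows]
            if L:
                mat = np.array([list(r) for r in rows])
                gaps = (mat == "-").reshape(len(rows), L // 3, 3).sum(axis=2)
                bad_codon = ((gaps == 1) | (gaps == 2)).any(axis=0)
                keep = np.repeat(~bad_codon, 3)
                rows = ["".join(np.compress(keep, list(r))) for r in rows]
        if not rows or not rows[0]:
            warnings.warn(f"gene {f.feature_id!r}: nothing left after trimming")
            continue
        out[f.feature_id] = Alignment(list(aln.names), rows)
    return out
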