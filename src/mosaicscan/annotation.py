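"""Genome-annotation input: GFF3 and GenBank feature tables.

Only the two feature kinds the breakpoint tests and gene extraction need
(``gene`` and ``CDS``) are retained.  File coordinates are 1-based inclusive
per convention; everything downstream of the readers is 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .errors import AlignmentFormatError, CoordinateError


@dataclass(frozen=True)
class Feature:
    feature_id: str
    type: str  # 'gene' or 'CDS'
    intervals: tuple[tuple[int, int], ...]  # 0-based half-open, transcription order
    strand: str  # '+' or '-'
    phase: tuple[int, ...] = ()  # per interval; empty -> all zero

    def __post_init__(self):
        for (s, e) in self.intervals:
            if not (0 <= s < e):
                raise CoordinateError(f"bad interval {(s, e)} in {self.feature_id}")

    @property
    def span(self) -> tuple[int, int]:
        cols = [c for iv in self.intervals for c in iv]
        return min(cols), max(cols)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass
class AnnotationTrack:
    """gene/CDS intervals in alignment coordinates."""

    features: list[Feature] = field(default_factory=list)

    def validate(self, aln_len: int) -> None:
        for f in self.features:
            for (s, e) in f.intervals:
                if e > aln_len:
                    raise CoordinateError(
                        f"feature {f.feature_id!r} interval ({s + 1}..{e}) "
                        f"exceeds alignment length {aln_len}"
                    )

    def of_type(self, ftype: str) -> list[Feature]:
        return [f for f in self.features if f.type == ftype]


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_ID_RE = re.compile(r"(?:^|;)\s*ID=([^;]+)")
_PARENT_RE = re.compile(r"(?:^|;)\s*Parent=([^;]+)")
_NAME_RE = re.compile(r"(?:^|;)\s*Name=([^;]+)")


def _gff_feature_id(attrs: str, fallback: str) -> str:
    for rx in (_ID_RE, _NAME_RE, _PARENT_RE):
        m = rx.search(attrs)
        if m:
            return m.group(1).strip()
    return fallback


def _read_gff3(path: str | Path) -> AnnotationTrack:
    # keyed by (feature_id, type): multi-interval CDS arrive as several rows
    parts: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    strands: dict[tuple[str, str], str] = {}
    order: list[tuple[str, str]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise AlignmentFormatError(
                    f"{path}:{ln}: expected 9 tab-separated columns"
                )
            _, _, ftype, start, end, _, strand, phase, attrs = cols
            if ftype not in ("gene", "CDS"):
                continue
            if strand not in "+-":
                raise AlignmentFormatError(
                    f"{path}:{ln}: unknown strand symbol {strand!r}"
                )
            s, e = int(start) - 1, int(end)  # 1-based incl. -> 0-based half-open
            if s < 0 or s >= e:
                raise CoordinateError(f"{path}:{ln}: bad coordinates {start}..{end}")
            ph = int(phase) if phase in ("0", "1", "2") else 0
            key = (_gff_feature_id(attrs, f"{ftype}_{ln}"), ftype)
            if key not in parts:
                parts[key] = []
                order.append(key)
            parts[key].append((s, e, ph))
            strands[key] = strand
    track = AnnotationTrack()
    for key in order:
        fid, ftype = key
        ivs = sorted(parts[key])
        strand = strands[key]
        if strand == "-":  # transcription order = descending coordinates
            ivs = ivs[::-1]
        track.features.append(
            Feature(
                feature_id=fid,
                type=ftype,
                intervals=tuple((s, e) for s, e, _ in ivs),
                strand=strand,
                phase=tuple(p for _, _, p in ivs),
            )
        )
    return track


# ---------------------------------------------------------------------------
# GenBank feature table (FEATURES block only)
# ---------------------------------------------------------------------------

_LOC_RANGE = re.compile(r"[<>]?(\d+)\.\.[<>]?(\d+)")
_LOC_SINGLE = re.compile(r"^[<>]?(\d+)$")


def _parse_location(loc: str) -> tuple[list[tuple[int, int]], str]:
    """Parse a GenBank location string into 0-based half-open intervals.

    Supports ``join(...)``, ``complement(...)``, single positions and plain
    ranges, which covers the feature tables this tool consumes.
    """
    loc = loc.replace(" ", "")
    strand = "+"
    if loc.startswith("complement(") and loc.endswith(")"):
        strand = "-"
        loc = loc[len("complement(") : -1]
    if loc.startswith("join(") and loc.endswith(")"):
        loc = loc[len("join(") : -1]
    intervals: list[tuple[int, int]] = []
    for token in loc.split(","):
        if token.startswith("complement(") and token.endswith(")"):
            strand = "-"
            token = token[len("complement(") : -1]
        m = _LOC_RANGE.fullmatch(token)
        if m:
            a, b = int(m.group(1)), int(m.group(2))
            intervals.append((a - 1, b))
            continue
        m = _LOC_SINGLE.fullmatch(token)
        if m:
            a = int(m.group(1))
            intervals.append((a - 1, a))
            continue
        raise AlignmentFormatError(f"unsupported GenBank location token {token!r}")
    if strand == "-":  # transcription order
        intervals = sorted(intervals)[::-1]
    else:
        intervals = sorted(intervals)
    return intervals, strand


_QUAL_RE = re.compile(r'^/(\w+)=?"?([^"]*)"?$')


def _read_genbank(path: str | Path) -> AnnotationTrack:
    lines = Path(path).read_text().splitlines()
    # isolate the FEATURES block
    start = None
    for i, line in enumerate(lines):
        if line.startswith("FEATURES"):
            start = i + 1
            break
    if start is None:
        # tolerate a bare feature table with no FEATURES header
        start = 0
    entries: list[tuple[str, str, list[str]]] = []  # (type, location, quals)
    cur: tuple[str, str, list[str]] | None = None
    for line in lines[start:]:
        if line[:1] not in (" ", ""):
            break  # next top-level section (ORIGIN, etc.)
        stripped = line.strip()
        if not stripped:
            continue
        indent = len(line) - len(line.lstrip())
        if indent == 5 and not stripped.startswith("/"):
            # new feature line: "     CDS             join(1..6,10..15)"
            parts = stripped.split(None, 1)
            if len(parts) != 2:
                raise AlignmentFormatError(f"bad feature line: {line!r}")
            cur = (parts[0], parts[1], [])
            entries.append(cur)
        elif cur is not None:
            if stripped.startswith("/"):
                cur[2].append(stripped)
            else:  # continuation of a wrapped location
                entries[-1] = (cur[0], cur[1] + stripped, cur[2])
                cur = entries[-1]
    track = AnnotationTrack()
    counter = 0
    for ftype, loc, quals in entries:
        if ftype not in ("gene", "CDS"):
            continue
        counter += 1
        fid = f"{ftype}_{counter}"
        for q in quals:
            m = _QUAL_RE.match(q)
            if m and m.group(1) in ("gene", "locus_tag", "label"):
                fid = m.group(2)
                break
        intervals, strand = _parse_location(loc)
        track.features.append(
            Feature(
                feature_id=fid,
                type=ftype,
                intervals=tuple(intervals),
                strand=strand,
                phase=tuple(0 for _ in intervals),
            )
        )
    return track


def read_annotation(path: str | Path, format: str = "auto") -> AnnotationTrack:
    """Read gene/CDS features from a GFF3 file or a GenBank feature table."""
    if format == "auto":
        head = Path(path).read_text()[:4096]
        if head.startswith("##gff") or "\tCDS\t" in head or "\tgene\t" in head:
            format = "gff3"
        else:
            format = "genbank"
    if format == "gff3":
        return _read_gff3(path)
    if format == "genbank":
        return _read_genbank(path)
    raise AlignmentFormatError(f"unknown annotation format {format!r}")
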