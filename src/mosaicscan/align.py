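"""Alignment container, readers/writers and per-column utilities.

Coordinates are 0-based half-open everywhere inside the library; file formats
and reports use the 1-based inclusive convention of the field.  IUPAC
ambiguity codes and gaps are treated as missing data throughout: they never
count as partial matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentFormatError,
    AlignmentShapeError,
    CharacterError,
    DuplicateNameError,
    SelfComparisonError,
)

#: residues kept verbatim after normalization ('U' is mapped to 'T' on read)
ALLOWED_CHARS = frozenset("ACGTRYSWKMBDHVN-")

#: unambiguous nucleotide -> small integer; anything else encodes as -1
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


class Alignment:
    """A rectangular, named nucleotide alignment.

    Parameters
    ----------
    names : sequence of str
        Unique identifiers, order preserved.
    rows : sequence of str
        Equal-length uppercase strings over ``ALLOWED_CHARS``.
    """

    __slots__ = ("names", "rows", "_codes")

    def __init__(self, names: Sequence[str], rows: Sequence[str]):
        names = list(names)
        rows = [str(r).upper().replace("U", "T") for r in rows]
        if len(names) != len(rows):
            raise AlignmentShapeError(
                f"{len(names)} names but {len(rows)} rows"
            )
        if len(set(names)) != len(names):
            seen, dup = set(), None
            for n in names:
                if n in seen:
                    dup = n
                    break
                seen.add(n)
            raise DuplicateNameError(f"duplicate sequence identifier {dup!r}")
        if rows:
            L = len(rows[0])
            for n, r in zip(names, rows):
                if len(r) != L:
                    raise AlignmentShapeError(
                        f"sequence {n!r} has length {len(r)}, expected {L}"
                    )
            if L < 1:
                raise AlignmentShapeError("alignment has zero columns")
            for n, r in zip(names, rows):
                for col, ch in enumerate(r):
                    if ch not in ALLOWED_CHARS:
                        raise CharacterError(
                            f"illegal character {ch!r} in sequence {n!r} "
                            f"at column {col + 1}"
                        )
        self.names = names
        self.rows = rows
        self._codes: np.ndarray | None = None

    # -- basic interface ---------------------------------------------------
    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def index(self, name: str) -> int:
        return self.names.index(name)

    def codes(self) -> np.ndarray:
        """(n_seqs, length) int8 matrix; A,C,G,T -> 0..3, missing -> -1."""
        if self._codes is None:
            lut = np.full(128, -1, dtype=np.int8)
            for ch, v in _CODE.items():
                lut[ord(ch)] = v
            buf = np.frombuffer(
                "".join(self.rows).encode("ascii"), dtype=np.uint8
            ).reshape(self.n_seqs, self.length)
            self._codes = lut[buf]
        return self._codes

    def gap_matrix(self) -> np.ndarray:
        """(n_seqs, length) bool matrix of gap ('-') positions."""
        buf = np.frombuffer(
            "".join(self.rows).encode("ascii"), dtype=np.uint8
        ).reshape(self.n_seqs, self.length)
        return buf == ord("-")

    def take_rows(self, idx: Iterable[int]) -> "Alignment":
        idx = list(idx)
        return Alignment([self.names[i] for i in idx], [self.rows[i] for i in idx])

    def slice_columns(self, start: int, end: int) -> "Alignment":
        return Alignment(self.names, [r[start:end] for r in self.rows])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.names == other.names
            and self.rows == other.rows
        )

    def __repr__(self) -> str:
        return f"<Alignment {self.n_seqs} sequences x {self.length} columns>"


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

_FORMAT_ALIASES = {"fasta": "fasta", "phylip": "phylip", "nexus": "nexus"}


def sniff_format(path: str | Path) -> str:
    """Guess the alignment format from the first non-blank line."""
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s:
                continue
            if s.startswith(">"):
                return "fasta"
            if s.upper().startswith("#NEXUS"):
                return "nexus"
            if s.split() and s.split()[0].isdigit():
                return "phylip"
            raise AlignmentFormatError(
                f"cannot determine alignment format of {path}"
            )
    raise AlignmentFormatError(f"{path} is empty")


def _from_records(records) -> Alignment:
    names, rows = [], []
    for rec in records:
        names.append(rec.id)
        rows.append(str(rec.seq))
    if not names:
        raise AlignmentFormatError("no sequences found")
    return Alignment(names, rows)


def read_alignment(path: str | Path, format: str = "auto") -> Alignment:
    """Read a FASTA / PHYLIP (sequential or interleaved) / NEXUS alignment.

    Lowercase is normalized to uppercase and 'U' to 'T'.  Errors name the
    offending sequence (ragged rows), identifier (duplicates) or column
    (illegal characters).
    """
    fmt = sniff_format(path) if format == "auto" else format
    if fmt not in _FORMAT_ALIASES:
        raise AlignmentFormatError(f"unknown alignment format {fmt!r}")
    if fmt == "fasta":
        # SeqIO so that ragged inputs reach our own shape check
        return _from_records(SeqIO.parse(str(path), "fasta"))
    _OWN_ERRORS = (AlignmentShapeError, DuplicateNameError, CharacterError)
    if fmt == "phylip":
        last_err: Exception | None = None
        for sub in ("phylip-relaxed", "phylip-sequential", "phylip"):
            try:
                return _from_records(AlignIO.read(str(path), sub))
            except Exception as exc:  # Biopython raises bare ValueError
                last_err = exc
        raise AlignmentFormatError(f"cannot parse PHYLIP file {path}: {last_err}")
    try:
        return _from_records(AlignIO.read(str(path), "nexus"))
    except _OWN_ERRORS:
        raise
    except Exception as exc:
        raise AlignmentFormatError(f"cannot parse NEXUS file {path}: {exc}")


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    """Write in FASTA, relaxed-name sequential PHYLIP, or NEXUS."""
    if aln.n_seqs == 0:
        raise AlignmentShapeError("refusing to write an empty alignment")
    if format not in _FORMAT_ALIASES:
        raise AlignmentFormatError(f"unknown alignment format {format!r}")
    records = [
        SeqRecord(Seq(row), id=name, description="")
        for name, row in zip(aln.names, aln.rows)
    ]
    msa = MultipleSeqAlignment(records)
    for rec in msa:
        rec.annotations["molecule_type"] = "DNA"
    biofmt = {"fasta": "fasta", "phylip": "phylip-relaxed", "nexus": "nexus"}[format]
    with open(path, "w") as fh:
        AlignIO.write(msa, fh, biofmt)


# ---------------------------------------------------------------------------
# per-column classification
# ---------------------------------------------------------------------------

SITE_LABELS = (
    "invariant",
    "biallelic_informative",
    "biallelic_singleton",
    "multiallelic",
    "gapped_excluded",
)


@dataclass(frozen=True)
class SiteClass:
    label: str
    minor_count: int


def classify_sites(aln: Alignment, max_missing_frac: float = 0.2) -> list[SiteClass]:
    """Label every column.

    Gaps and ambiguity codes count as missing.  A column whose missing
    fraction exceeds ``max_missing_frac`` is ``gapped_excluded`` regardless
    of its states; otherwise the label depends on the number of distinct
    non-missing states and the minor-allele count.
    """
    codes = aln.codes()
    n, L = codes.shape
    out: list[SiteClass] = []
    counts = np.stack([(codes == s).sum(axis=0) for s in range(4)])  # (4, L)
    missing = (codes < 0).sum(axis=0)
    for j in range(L):
        cnt = counts[:, j]
        present = cnt[cnt > 0]
        if n and missing[j] / n > max_missing_frac:
            out.append(SiteClass("gapped_excluded", 0))
            continue
        k = len(present)
        if k <= 1:
            out.append(SiteClass("invariant", 0))
        elif k == 2:
            minor = int(present.min())
            label = "biallelic_informative" if minor >= 2 else "biallelic_singleton"
            out.append(SiteClass(label, minor))
        else:
            srt = np.sort(present)
            out.append(SiteClass("multiallelic", int(srt[:-1].sum())))
    return out


def parsimony_informative_columns(codes: np.ndarray) -> np.ndarray:
    """Indices of columns with >= 2 states each carried by >= 2 sequences."""
    counts = np.stack([(codes == s).sum(axis=0) for s in range(4)])
    return np.flatnonzero((counts >= 2).sum(axis=0) >= 2)


# ---------------------------------------------------------------------------
# identity / distance helpers
# ---------------------------------------------------------------------------

def pairwise_identity(
    aln: Alignment, i: int, j: int, window: tuple[int, int] | None = None
) -> float:
    """Fraction of identical residues between rows *i* and *j*.

    Columns where either row is missing (gap or ambiguity) are excluded from
    both numerator and denominator.  Returns ``nan`` when no column is
    comparable.
    """
    if i == j:
        raise SelfComparisonError("pairwise_identity requires i != j")
    start, end = window if window is not None else (0, aln.length)
    if not (0 <= start < end <= aln.length):
        raise ValueError(f"bad window {(start, end)} for length {aln.length}")
    codes = aln.codes()
    a, b = codes[i, start:end], codes[j, start:end]
    ok = (a >= 0) & (b >= 0)
    n = int(ok.sum())
    if n == 0:
        return float("nan")
    return float((a[ok] == b[ok]).sum() / n)


def p_distance_matrix(aln: Alignment) -> np.ndarray:
    """Pairwise-deletion proportion of differing sites; nan when no overlap."""
    codes = aln.codes()
    n = aln.n_seqs
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = codes[i], codes[j]
            ok = (a >= 0) & (b >= 0)
            m = int(ok.sum())
            p = float((a[ok] != b[ok]).sum() / m) if m else float("nan")
            out[i, j] = out[j, i] = p
    return out


def reverse_complement(row: str) -> str:
    return row.translate(COMPLEMENT)[::-1]
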