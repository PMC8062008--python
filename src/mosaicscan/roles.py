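"""Query-vs-reference scanning.

Instead of testing every sequence against every pair, designated query
sequences are tested for recombination between designated reference
sequences.  Roles come from naming tags ("[Q]", "[R]", "[R:group]") or from
explicit list files; with several reference groups only cross-group parent
pairs are examined.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

from .align import Alignment
from .errors import ConfigError
from .scan import RecombinationEvent, ScanConfig, scan_all

_TAG_RE = re.compile(r"\[(Q|R)(?::([^\]]+))?\]")


@dataclass
class RoleAssignment:
    role: dict[str, str]  # name -> 'query' | 'reference' | 'ignored'
    reference_group: dict[str, str] = field(default_factory=dict)

    @property
    def queries(self) -> list[str]:
        return [n for n, r in self.role.items() if r == "query"]

    @property
    def references(self) -> list[str]:
        return [n for n, r in self.role.items() if r == "reference"]

    @property
    def groups(self) -> set[str]:
        return set(self.reference_group.values())

    def validate(self) -> None:
        if not self.queries:
            raise ConfigError("no query sequences designated")
        if len(self.references) < 2:
            raise ConfigError("need >= 2 reference sequences")


def _read_list(path: str | Path) -> list[str]:
    return [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]


def assign_roles(
    names: list[str],
    rule: str = "tags",
    query_list: str | Path | None = None,
    ref_list: str | Path | None = None,
) -> RoleAssignment:
    """Designate each sequence query / reference / ignored.

    tags mode: a name containing "[Q]" is a query; "[R]" or "[R:<group>]"
    a reference (group defaults to "all"); untagged names are ignored.
    lists mode: membership files decide; a name in both files is an error.
    """
    role: dict[str, str] = {}
    group: dict[str, str] = {}
    if rule == "tags":
        for n in names:
            m = _TAG_RE.search(n)
            if not m:
                role[n] = "ignored"
            elif m.group(1) == "Q":
                role[n] = "query"
            else:
                role[n] = "reference"
                group[n] = m.group(2) or "all"
    elif rule == "lists":
        if query_list is None or ref_list is None:
            raise ConfigError("lists mode requires both query and reference files")
        q = set(_read_list(query_list))
        r = set(_read_list(ref_list))
        both = q & r
        if both:
            raise ConfigError(f"sequences in both lists: {sorted(both)}")
        for n in names:
            if n in q:
                role[n] = "query"
            elif n in r:
                role[n] = "reference"
                group[n] = "all"
            else:
                role[n] = "ignored"
    else:
        raise ConfigError(f"unknown role rule {rule!r}")
    out = RoleAssignment(role, group)
    out.validate()
    return out


def admissible_triplets(
    aln: Alignment, roles: RoleAssignment
) -> list[tuple[int, int, int]]:
    """(query, ref1, ref2) index triplets; cross-group when > 1 group."""
    idx = {n: i for i, n in enumerate(aln.names)}
    queries = [idx[n] for n in roles.queries if n in idx]
    refs = [n for n in roles.references if n in idx]
    if not queries:
        raise ConfigError("no query sequence present in the alignment")
    if len(refs) < 2:
        raise ConfigError("fewer than 2 reference sequences in the alignment")
    multi = len(roles.groups) > 1
    pairs = []
    for r1, r2 in combinations(refs, 2):
        if multi and roles.reference_group[r1] == roles.reference_group[r2]:
            continue
        pairs.append((idx[r1], idx[r2]))
    if not pairs:
        raise ConfigError("no eligible reference pair (check group labels)")
    return [(q, r1, r2) for q in queries for (r1, r2) in pairs]


def query_scan(
    aln: Alignment,
    roles: RoleAssignment,
    cfg: ScanConfig | None = None,
) -> list[RecombinationEvent]:
    """Scan only (query, reference, reference) triplets.

    The query is the only admissible recombinant; events whose inferred
    recombinant is a reference are discarded.  Consolidation is per query.
    """
    roles.validate()
    trips = admissible_triplets(aln, roles)
    events = scan_all(
        aln,
        cfg,
        triplets=trips,
        admissible_recombinants=set(roles.queries),
    )
    grp = roles.reference_group
    out = []
    for e in events:
        method = (
            f"{e.method};groups="
            f"{grp.get(e.major_parent, '?')}|{grp.get(e.minor_parent, '?')}"
        )
        out.append(
            RecombinationEvent(
                recombinant=e.recombinant,
                major_parent=e.major_parent,
                minor_parent=e.minor_parent,
                breakpoints=e.breakpoints,
                p_raw=e.p_raw,
                p_corrected=e.p_corrected,
                flags=e.flags,
                method=method,
            )
        )
    return out
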