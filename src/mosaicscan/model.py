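"""Model-style front door: build a scan from data, fit, inspect results.

``RecombinationScan`` holds the alignment and configuration;  ``fit()``
runs the triplet scan (optionally restricted to query-vs-reference
triplets), vets each event against false-positive signatures, and returns a
``ScanResults`` carrying the event table, diagnostics, surgery methods and
downstream tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import surgery, trees
from .align import Alignment, read_alignment
from .annotation import AnnotationTrack
from .bktests import (
    BreakpointSet,
    breakpoint_density,
    breakpoint_region_test,
    partition_columns,
)
from .filters import PhiResult, VetConfig, phi_test, vet_event
from .roles import RoleAssignment, query_scan
from .scan import RecombinationEvent, ScanConfig, events_to_frame, scan_all


class RecombinationScan:
    """Triplet-scan recombination model for one nucleotide alignment.

    Parameters
    ----------
    alignment : Alignment
    config : ScanConfig, optional
    roles : RoleAssignment, optional
        When given, the scan runs in query-vs-reference mode.

    Examples
    --------
    >>> from mosaicscan import simulate_clonal, implant_events
    >>> aln, tree = simulate_clonal(10, 5000, 0.1, seed=1)
    >>> aln, truth = implant_events(aln, tree, 1, 800, 1500, 0.1, seed=2)
    >>> res = RecombinationScan(aln).fit()
    >>> len(res.events) >= 1
    True
    """

    def __init__(
        self,
        alignment: Alignment,
        config: ScanConfig | None = None,
        roles: RoleAssignment | None = None,
        vet_config: VetConfig | None = None,
    ):
        self.alignment = alignment
        self.config = config or ScanConfig()
        self.roles = roles
        self.vet_config = vet_config or VetConfig(seed=self.config.seed)

    @classmethod
    def from_file(
        cls,
        path,
        format: str = "auto",
        config: ScanConfig | None = None,
        roles: RoleAssignment | None = None,
    ) -> "RecombinationScan":
        return cls(read_alignment(path, format), config=config, roles=roles)

    def fit(self, vet: bool = True) -> "ScanResults":
        """Run the scan; optionally vet each event for false positives."""
        if self.roles is not None:
            events = query_scan(self.alignment, self.roles, self.config)
        else:
            events = scan_all(self.alignment, self.config)
        if vet:
            events = [
                vet_event(e, self.alignment, self.vet_config) for e in events
            ]
        return ScanResults(self, events)


@dataclass
class ScanResults:
    """Detected events plus everything one does with them."""

    model: RecombinationScan
    events: list[RecombinationEvent]

    @property
    def alignment(self) -> Alignment:
        return self.model.alignment

    @property
    def events_frame(self) -> pd.DataFrame:
        return events_to_frame(self.events)

    @property
    def unflagged_events(self) -> list[RecombinationEvent]:
        return [e for e in self.events if not e.flags]

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        aln = self.alignment
        cfg = self.model.config
        lines = [
            "Recombination triplet scan",
            "=" * 62,
            f"Sequences: {aln.n_seqs}    Columns: {aln.length}",
            f"Window: {cfg.window} informative sites   alpha: {cfg.alpha}"
            f"   correction: {cfg.bonferroni_factor_mode}",
            f"Events detected: {len(self.events)} "
            f"({len(self.unflagged_events)} unflagged)",
            "-" * 62,
        ]
        df = self.events_frame
        if df.empty:
            lines.append("(no events)")
        else:
            lines.append(df.to_string(index=False))
        return "\n".join(lines)

    # -- dataset surgery ---------------------------------------------------
    def strip(self, include_flagged: bool = False) -> Alignment:
        return surgery.strip_recombinants(
            self.alignment, self.events, include_flagged
        )

    def mask(
        self, missing_char: str = "N", include_flagged: bool = False
    ) -> Alignment:
        return surgery.mask_recombinant_fragments(
            self.alignment, self.events, missing_char, include_flagged
        )

    def split(
        self, missing_char: str = "N", include_flagged: bool = False
    ) -> Alignment:
        return surgery.split_recombinants(
            self.alignment, self.events, missing_char, include_flagged
        )

    def partition(self, include_flagged: bool = False):
        evs = self.events if include_flagged else self.unflagged_events
        return surgery.partition_alignment(self.alignment, evs)

    # -- breakpoint statistics ---------------------------------------------
    def breakpoint_set(self, collapse_per_event: bool = False) -> BreakpointSet:
        return BreakpointSet.from_events(
            self.unflagged_events, self.alignment.length, collapse_per_event
        )

    def region_test(
        self,
        annotation: AnnotationTrack,
        scheme: str,
        edge_frac: float = 0.1,
        n_perm: int = 10000,
        seed: int | None = None,
    ) -> pd.DataFrame:
        part = partition_columns(annotation, self.alignment.length, scheme, edge_frac)
        return breakpoint_region_test(
            self.breakpoint_set(),
            part,
            n_perm=n_perm,
            seed=self.model.config.seed if seed is None else seed,
        )

    def density(self, window: int = 200, step: int = 50) -> pd.DataFrame:
        return breakpoint_density(
            self.breakpoint_set(), self.alignment.length, window, step
        )

    # -- downstream --------------------------------------------------------
    def phi(self, w: int = 100, n_perm: int = 1000, seed: int | None = None) -> PhiResult:
        return phi_test(
            self.alignment,
            w=w,
            n_perm=n_perm,
            seed=self.model.config.seed if seed is None else seed,
        )

    def trees(self, min_sites: int = 100):
        parts, _table = self.partition()
        return trees.trees_per_partition(parts, min_sites=min_sites)
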