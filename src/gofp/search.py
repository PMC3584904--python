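"""Searching a query sequence against the profile library.

Each hit is a local match of a query segment against one (fold, GO term)
profile entry, i.e. a *concomitant* prediction of structural fold and
molecular function for that segment of the query — the segment is the
predicted domain.  On top of the hit, the entry's conserved columns mapped
through the alignment point at candidate functional residues of the query
(positions conserved for purely structural reasons show up too; the package
asserts only the mapping, not the biology).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .align import EvalueParams, LocalAlignmentTrace, evalue, profile_sw
from .library import ProfileEntry, ProfileLibrary
from .pssm import conservation_fraction

logger = logging.getLogger(__name__)

DEFAULT_MAX_EVALUE = 10.0


@dataclass
class Hit:
    """One fold+function prediction for a segment of the query."""

    query_id: str
    fold_id: str
    go_id: str
    trace: LocalAlignmentTrace
    score: float
    evalue: float
    #: extra GO terms carried by the matched database object (used by the
    #: single-sequence comparator, whose domains may carry several terms).
    candidate_go_ids: frozenset[str] = frozenset()

    @property
    def entry_ref(self) -> tuple[str, str]:
        return (self.fold_id, self.go_id)

    @property
    def query_interval(self) -> tuple[int, int]:
        return self.trace.query_interval

    def all_go_ids(self) -> frozenset[str]:
        return self.candidate_go_ids | {self.go_id}

    def sort_key(self) -> tuple:
        return (self.evalue, -self.score, self.fold_id, self.go_id)


@dataclass
class SitePrediction:
    """Conserved profile columns mapped onto query residues."""

    query_positions: list[int]
    details: list[dict] = field(default_factory=list)
    missing_sites: list[int] = field(default_factory=list)


def search_library(
    query_id: str,
    query_sequence: str,
    library: ProfileLibrary,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> list[Hit]:
    """Profile-SW the query against every entry; keep hits with E <= cutoff.

    Hits are sorted by E-value ascending, ties by score descending, then by
    (fold_id, go_id) — a total deterministic order.
    """
    if not query_sequence:
        raise ValueError("empty query sequence")
    if not library.entries:
        logger.warning("searching an empty library: no hits possible")
        return []
    hits: list[Hit] = []
    m = len(query_sequence)
    for entry in library.entries:
        trace = profile_sw(
            query_sequence, entry.pssm,
            gap_open=library.params.profile_gap_open,
            gap_extend=library.params.profile_gap_extend,
        )
        if trace.score <= 0:
            continue
        params = entry.evalue_params.with_query_length(m)
        e = evalue(trace.score, params)
        if e <= max_evalue:
            hits.append(Hit(
                query_id=query_id,
                fold_id=entry.fold_id,
                go_id=entry.go_id,
                trace=trace,
                score=trace.score,
                evalue=e,
            ))
    hits.sort(key=Hit.sort_key)
    return hits


def top_hit(hits: list[Hit]) -> Hit | None:
    """First hit under the search ordering, or None for an empty list."""
    return hits[0] if hits else None


def filter_overlaps(hits: list[Hit], max_overlap: float = 0.25) -> list[Hit]:
    """Optional greedy non-overlap filter for multi-domain interpretation.

    Best hit first; a hit is discarded when it overlaps an accepted hit by
    more than ``max_overlap`` of its own length.
    """
    accepted: list[Hit] = []
    for h in sorted(hits, key=Hit.sort_key):
        s, e = h.query_interval
        length = max(e - s, 1)
        overlap = 0
        for a in accepted:
            as_, ae = a.query_interval
            overlap = max(overlap, min(e, ae) - max(s, as_))
        if overlap <= max_overlap * length:
            accepted.append(h)
    return accepted


def predict_sites(hit: Hit, entry: ProfileEntry, query_sequence: str) -> SitePrediction:
    """Map the entry's conserved columns onto query residues via the hit.

    Conserved columns matched in the trace are reported as candidate
    functional residues (with the column consensus and conservation
    fraction); conserved columns that the trace gaps in the query are
    reported separately as missing sites.
    """
    if hit.entry_ref != (entry.fold_id, entry.go_id):
        raise ValueError("hit does not belong to the given entry")
    q2c = hit.trace.query_for_column()
    positions: list[int] = []
    details: list[dict] = []
    missing: list[int] = []
    lo = min(q2c) if q2c else None
    hi = max(q2c) if q2c else None
    for col in sorted(entry.conserved):
        qpos = q2c.get(col)
        if qpos is not None:
            positions.append(qpos)
            details.append({
                "query_position": qpos,
                "profile_column": col,
                "consensus_residue": entry.pssm.consensus(col),
                "query_residue": query_sequence[qpos].upper(),
                "conservation_fraction": conservation_fraction(entry.alignment, col),
            })
        elif lo is not None and lo <= col <= hi:
            missing.append(col)
    return SitePrediction(
        query_positions=positions, details=details, missing_sites=missing
    )
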