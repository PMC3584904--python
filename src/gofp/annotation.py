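"""Transfer of whole-chain GO:MF annotations to individual domains.

Functional annotations in structure databases are attached to whole chains,
but it is usually one particular domain that carries the molecular
function.  For each GO term, we look at the fold composition of every chain
annotated with it and find the *minimum set of folds* that explains all of
those chains (a minimum hitting set).  The term is then assigned to the
domains whose fold is in that cover.  Iterating over terms and accumulating
the assignments yields domain-level annotations from chain-level ones.

The procedure is a heuristic and is deliberately reproduced as such: chains
deposited as isolated fragments of multi-domain proteins, annotated with
the whole protein's function, can force a spurious fold into the cover (see
the fragment-artifact generator in :mod:`gofp.world`, which constructs
exactly this confound for testing).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from .ontology import GoDag

logger = logging.getLogger(__name__)

EXCLUSION_FLAGS = frozenset({"mutant", "circular_permutation"})

# Above this fold-universe size the exact hitting-set search (subset
# enumeration) is replaced by a greedy cover.
EXACT_UNIVERSE_LIMIT = 20


@dataclass
class DomainRecord:
    """One structural domain: the unit at which function is predicted."""

    domain_id: str
    chain_id: str
    fold_id: str
    sequence: str
    is_multidomain_entry: bool = False
    domain_go_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"domain {self.domain_id} has an empty sequence")
        if not self.fold_id:
            raise ValueError(f"domain {self.domain_id} has an empty fold id")


@dataclass
class ChainRecord:
    """One protein chain: an ordered list of domains plus chain-level terms."""

    chain_id: str
    domain_ids: list[str]
    chain_go_ids: set[str] = field(default_factory=set)
    cluster_id: str = ""
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.domain_ids:
            raise ValueError(f"chain {self.chain_id} has no domains")

    @property
    def excluded(self) -> bool:
        return bool(self.flags & EXCLUSION_FLAGS)


def minimal_fold_set(chain_fold_sets: list[set[str]]) -> set[str]:
    """Minimum hitting set over fold-id sets, with deterministic tie-break.

    Returns the smallest set of folds intersecting every input set; among
    equal-cardinality optima the lexicographically smallest (candidates
    compared as sorted tuples of fold ids).  Exact subset enumeration is
    used while the fold universe has at most ``EXACT_UNIVERSE_LIMIT``
    elements; beyond that a greedy largest-coverage-first cover (with
    lexicographic tie-break) is used and a downgrade notice is logged.
    """
    if not chain_fold_sets:
        raise ValueError("no evidence chains: cannot compute a fold cover")
    for s in chain_fold_sets:
        if not s:
            raise ValueError("an evidence chain has an empty fold set")
    universe = sorted(set().union(*chain_fold_sets))
    if len(universe) <= EXACT_UNIVERSE_LIMIT:
        for size in range(1, len(universe) + 1):
            # combinations() over the sorted universe yields candidates in
            # lexicographic order, so the first hit is the canonical optimum.
            for cand in itertools.combinations(universe, size):
                cand_set = set(cand)
                if all(cand_set & s for s in chain_fold_sets):
                    return cand_set
        raise AssertionError("unreachable: universe itself is a hitting set")
    logger.warning(
        "fold universe has %d elements (> %d): falling back to greedy cover",
        len(universe), EXACT_UNIVERSE_LIMIT,
    )
    remaining = [set(s) for s in chain_fold_sets]
    cover: set[str] = set()
    while remaining:
        coverage = {f: sum(1 for s in remaining if f in s) for f in universe}
        top = max(coverage.values())
        best = min(f for f, c in coverage.items() if c == top)
        cover.add(best)
        remaining = [s for s in remaining if best not in s]
    return cover


def assign_domain_annotations(
    chains: list[ChainRecord],
    domains: list[DomainRecord],
    dag: GoDag,
    exclude_flagged: bool = True,
) -> list[DomainRecord]:
    """Annotate domains from chain-level GO terms via per-term fold covers.

    For each GO term, the evidence is the set of (unflagged) chains carrying
    it; the minimal fold cover of their fold compositions decides which
    domains inherit the term.  Covers are computed independently per term
    and accumulate on the domains.  Chains flagged mutant or
    circular-permutation are excluded from evidence when
    ``exclude_flagged`` (the default, conservative choice).
    """
    by_id = {d.domain_id: d for d in domains}
    for c in chains:
        for did in c.domain_ids:
            if did not in by_id:
                raise ValueError(f"chain {c.chain_id} references unknown domain {did}")
            if by_id[did].chain_id != c.chain_id:
                raise ValueError(
                    f"domain {did} points to chain {by_id[did].chain_id}, "
                    f"not {c.chain_id}"
                )
    terms = sorted(set().union(*(c.chain_go_ids for c in chains)) if chains else set())
    for term in terms:
        if term not in dag:
            logger.warning("skipping term %s: absent from the ontology", term)
            continue
        evidence = [
            c for c in chains
            if term in c.chain_go_ids and not (exclude_flagged and c.excluded)
        ]
        if not evidence:
            continue
        fold_sets = [{by_id[d].fold_id for d in c.domain_ids} for c in evidence]
        cover = minimal_fold_set(fold_sets)
        for c in evidence:
            for did in c.domain_ids:
                if by_id[did].fold_id in cover:
                    by_id[did].domain_go_ids.add(term)
    return domains
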