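"""The GO molecular-function ontology as a rooted DAG.

Terms are linked by ``is_a`` edges only.  The quantity this package cares
about is a term's *distance to the root* (GO:0003674, molecular_function),
used as a broadness proxy: terms close to the root ("catalytic activity")
are too unspecific to be worth predicting, so both the profile-library
build and the benchmark filter on a minimum depth.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

MF_ROOT = "GO:0003674"
MF_NAMESPACE = "molecular_function"


@dataclass(frozen=True)
class GoTerm:
    """One ontology term; ``parent_ids`` are the direct is_a parents."""

    id: str
    name: str
    parent_ids: tuple[str, ...] = ()
    obsolete: bool = False


class GoDag:
    """Rooted acyclic is_a graph over GO terms, with cached depth queries."""

    def __init__(self, terms: dict[str, GoTerm], root_id: str):
        self.terms = terms
        self.root_id = root_id
        self._depth_cache: dict[str, dict[str, int]] = {}
        self._validate()

    def _validate(self) -> None:
        if self.root_id not in self.terms:
            raise ValueError(f"root {self.root_id} missing from term map")
        if self.terms[self.root_id].parent_ids:
            raise ValueError("root term must have no parents")
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t in self.terms.values():
            for p in t.parent_ids:
                if p not in self.terms:
                    raise ValueError(f"unresolved parent {p} of {t.id}")
                g.add_edge(t.id, p)
        if not nx.is_directed_acyclic_graph(g):
            u, v, *_ = next(iter(nx.find_cycle(g)))
            raise ValueError(f"ontology contains a cycle through edge {u} -> {v}")
        for t in self.terms.values():
            if t.obsolete:
                if t.parent_ids:
                    raise ValueError(f"obsolete term {t.id} must have no parents")
            elif t.id != self.root_id and not nx.has_path(g, t.id, self.root_id):
                raise ValueError(f"term {t.id} cannot reach root {self.root_id}")
        self._graph = g

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def distance_to_root(self, term_id: str, mode: str = "shortest") -> int:
        """Length of the shortest (default) or longest is_a path to the root.

        Shortest-path distance is the convention used everywhere in this
        package as the broadness proxy; ``mode="longest"`` is exposed for
        sensitivity analysis only.
        """
        if term_id not in self.terms:
            raise KeyError(f"unknown GO term {term_id}")
        if self.terms[term_id].obsolete:
            raise ValueError(f"obsolete term {term_id} has no defined depth")
        if mode not in ("shortest", "longest"):
            raise ValueError(f"unknown depth mode {mode!r}")
        cache = self._depth_cache.get(mode)
        if cache is None:
            cache = self._compute_depths(mode)
            self._depth_cache[mode] = cache
        return cache[term_id]

    def _compute_depths(self, mode: str) -> dict[str, int]:
        live = [t.id for t in self.terms.values() if not t.obsolete]
        if mode == "shortest":
            # BFS from the root over reversed edges.
            rev = self._graph.reverse(copy=False)
            return dict(nx.single_source_shortest_path_length(rev, self.root_id))
        depths = {self.root_id: 0}
        for node in reversed(list(nx.topological_sort(self._graph.subgraph(live)))):
            if node == self.root_id:
                continue
            depths[node] = 1 + max(depths[p] for p in self.terms[node].parent_ids)
        return depths

    def non_obsolete_ids(self) -> list[str]:
        return [t.id for t in self.terms.values() if not t.obsolete]


def parse_obo(obo_text: str, namespace: str = MF_NAMESPACE) -> GoDag:
    """Parse OBO 1.2 text into a :class:`GoDag`, keeping one namespace.

    Only ``[Term]`` stanzas are read (fields: id, name, namespace, is_a,
    is_obsolete).  is_a edges pointing outside the kept namespace are
    dropped with a warning; terms from other namespaces are absent from the
    result entirely.
    """
    graph = obonet.read_obo(io.StringIO(obo_text), ignore_obsolete=False)
    kept: dict[str, GoTerm] = {}
    raw: dict[str, dict] = {}
    for node, data in graph.nodes(data=True):
        ns = data.get("namespace", namespace)
        if ns != namespace:
            continue
        raw[node] = data
    for node, data in raw.items():
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        parents = []
        if not obsolete:
            for p in data.get("is_a", []):
                if p in raw:
                    parents.append(p)
                else:
                    logger.warning(
                        "dropping is_a edge %s -> %s (target outside %s)",
                        node, p, namespace,
                    )
        kept[node] = GoTerm(
            id=node,
            name=data.get("name", node),
            parent_ids=tuple(parents),
            obsolete=obsolete,
        )
    roots = [t.id for t in kept.values() if not t.obsolete and not t.parent_ids]
    if MF_ROOT in roots:
        root_id = MF_ROOT
    elif len(roots) == 1:
        root_id = roots[0]
    else:
        raise ValueError(f"cannot identify a unique root among {sorted(roots)}")
    # Terms whose every path to the root was severed by namespace filtering
    # are unreachable; drop them rather than fail validation.
    dag_terms = _prune_unreachable(kept, root_id)
    return GoDag(dag_terms, root_id)


def _prune_unreachable(terms: dict[str, GoTerm], root_id: str) -> dict[str, GoTerm]:
    g = nx.DiGraph()
    g.add_nodes_from(terms)
    for t in terms.values():
        for p in t.parent_ids:
            g.add_edge(t.id, p)
    keep: set[str] = {root_id}
    for t in terms.values():
        if t.obsolete:
            keep.add(t.id)
        elif nx.has_path(g, t.id, root_id):
            keep.add(t.id)
        else:
            logger.warning("dropping term %s: unreachable from root after filtering", t.id)
    out = {}
    for tid in keep:
        t = terms[tid]
        parents = tuple(p for p in t.parent_ids if p in keep)
        out[tid] = GoTerm(t.id, t.name, parents, t.obsolete)
    return out


def write_obo(terms: Iterable[GoTerm], namespace: str = MF_NAMESPACE) -> str:
    """Serialize terms to OBO 1.2 text (inverse of :func:`parse_obo`)."""
    chunks = ["format-version: 1.2", "ontology: go", ""]
    for t in sorted(terms, key=lambda t: t.id):
        chunks.append("[Term]")
        chunks.append(f"id: {t.id}")
        chunks.append(f"name: {t.name}")
        chunks.append(f"namespace: {namespace}")
        for p in t.parent_ids:
            chunks.append(f"is_a: {p}")
        if t.obsolete:
            chunks.append("is_obsolete: true")
        chunks.append("")
    return "\n".join(chunks)
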