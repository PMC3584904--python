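"""Seeded synthetic worlds with the statistical structure the method assumes.

The generator emulates, at desk scale, the ingredients the profile method
relies on:

* **folds** — each fold has an ancestral core sequence; all domains of the
  fold are descendants of it, so same-fold domains are alignable;
* **functions** — each GO:MF leaf term has a short sequence motif,
  implanted into the fold core at a fold-specific offset; motif columns
  evolve under strong purifying selection (a small multiplier on the
  background substitution rate), emulating conserved functional sites;
* **divergence tiers / clusters** — each (fold, function) cell is populated
  by several sequence-similarity clusters: a cluster founder is drawn at
  the cross-cluster divergence from the cell ancestor, and cluster members
  at the within-cluster divergence from their founder.  The cluster id
  plays the role of an identity-based chain cluster, without running any
  clustering;
* **chains** — mostly single-domain; a fraction of clusters are paired
  into two-domain chains (both domains sharing the chain's cluster id, so
  leave-cluster-out removes them together);
* **ontology** — a layered is_a DAG with one leaf term per function.

Substitutions are drawn from BLOSUM62-conditional target distributions so
that identity percentages and alignability behave like real divergent
homologs; indels have geometric lengths (mean 2) and never touch motif
columns.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .alphabet import blosum_conditional, decode, encode, robinson_background
from .annotation import ChainRecord, DomainRecord
from .ontology import GoDag, GoTerm, MF_ROOT

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WorldParams:
    """Study conditions of a synthetic world (all defaults are the
    conditions used by the package's own evaluation)."""

    n_folds: int = 4
    n_functions: int = 4
    domains_per_cell: int = 6
    clusters_per_cell: int = 5
    fold_core_length: int = 120
    motif_length: int = 8
    #: expected substitutions/site between the fold core and a cell's
    #: common ancestor (same fold, different function = different
    #: long-diverged superfamily; substitutions only, so fold positions
    #: stay comparable across cells)
    divergence_function: float = 0.05
    #: expected substitutions/site of a cluster founder from the cell
    #: ancestor (the mean of the per-cluster draw)
    divergence_cross: float = 0.55
    #: half-width of an optional uniform per-cluster spread around
    #: ``divergence_cross`` (homologous families at varying distances)
    divergence_cross_spread: float = 0.0
    #: expected substitutions/site of a member from its cluster founder
    divergence_within: float = 0.05
    #: multiplier on the substitution rate at motif columns (purifying
    #: selection on functional sites)
    motif_conservation: float = 0.05
    indel_rate: float = 0.01
    indel_mean_length: float = 2.0
    dag_depth: int = 4
    multidomain_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_folds", "n_functions", "domains_per_cell",
                     "clusters_per_cell", "fold_core_length", "motif_length",
                     "dag_depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("divergence_function", "divergence_cross",
                     "divergence_within", "motif_conservation", "indel_rate",
                     "multidomain_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.motif_length > self.fold_core_length:
            raise ValueError("motif longer than the fold core")
        if self.dag_depth < 2:
            raise ValueError("dag_depth must be >= 2")


@dataclass
class DomainTruth:
    fold_id: str
    go_ids: set[str]
    motif_positions: list[int]
    #: for each residue of the domain, the cell-ancestor position it
    #: descends from, or -1 for an inserted residue
    ancestor_map: list[int] = field(default_factory=list)


@dataclass
class SyntheticWorld:
    params: WorldParams
    dag: GoDag
    domains: list[DomainRecord]
    chains: list[ChainRecord]
    truth: dict[str, DomainTruth]

    def domains_by_id(self) -> dict[str, DomainRecord]:
        return {d.domain_id: d for d in self.domains}

    def chain_sequence(self, chain: ChainRecord) -> str:
        by_id = self.domains_by_id()
        return "".join(by_id[d].sequence for d in chain.domain_ids)

    def structural_aligner(self):
        """A binary aligner that plays the role of structural superposition.

        Two residues are aligned iff they descend from the same ancestral
        core position — which is what a structure alignment of two
        same-fold domains recovers, independently of how far their
        sequences have diverged.
        """
        return ancestry_aligner(self.truth, self.domains_by_id())


def ancestry_aligner(truth: dict[str, "DomainTruth"],
                     domains_by_id: dict[str, "DomainRecord"]):
    """Binary aligner over recorded ancestral homology (see
    :meth:`SyntheticWorld.structural_aligner`).  Returns a callable with
    the same signature as :func:`gofp.align.global_align`; ``id_a`` and
    ``id_b`` must be domain ids with recorded ancestor maps."""
    from .align import PairwiseAlignment
    from .alphabet import GAP

    def aligner(seq_a: str, seq_b: str, id_a: str = "", id_b: str = "",
                **_ignored) -> PairwiseAlignment:
        for did, seq in ((id_a, seq_a), (id_b, seq_b)):
            if did not in truth or not truth[did].ancestor_map:
                raise ValueError(f"no ancestry recorded for domain {did!r}")
            if domains_by_id[did].sequence != seq.upper():
                raise ValueError(f"sequence mismatch for domain {did!r}")
        ma, mb = truth[id_a].ancestor_map, truth[id_b].ancestor_map
        rows_a: list[str] = []
        rows_b: list[str] = []
        i = j = matched = 0
        while i < len(ma) or j < len(mb):
            a_anc = ma[i] if i < len(ma) else None
            b_anc = mb[j] if j < len(mb) else None
            if a_anc is not None and (
                a_anc == -1 or b_anc is None or (b_anc != -1 and a_anc < b_anc)
            ):
                rows_a.append(seq_a[i])
                rows_b.append(GAP)
                i += 1
            elif b_anc is not None and (
                b_anc == -1 or a_anc is None or (a_anc != -1 and b_anc < a_anc)
            ):
                rows_a.append(GAP)
                rows_b.append(seq_b[j])
                j += 1
            else:
                rows_a.append(seq_a[i])
                rows_b.append(seq_b[j])
                i += 1
                j += 1
                matched += 1
        return PairwiseAlignment(
            id_a=id_a, id_b=id_b,
            gapped_a="".join(rows_a), gapped_b="".join(rows_b),
            score=float(matched),
        )

    return aligner


def _mutate(
    seq: np.ndarray,
    anc_map: list[int],
    motif_anc: set[int],
    sub_rate: float,
    motif_sub_rate: float,
    indel_rate: float,
    indel_mean: float,
    rng: np.random.Generator,
    cond: np.ndarray,
    background: np.ndarray,
) -> tuple[np.ndarray, list[int]]:
    """One round of substitutions + indels; returns (sequence, ancestor map).

    Motif columns (identified through the ancestor map) substitute at the
    reduced rate and are never inserted into or deleted.
    """
    out: list[int] = []
    out_map: list[int] = []
    geom_p = 1.0 / max(indel_mean, 1.0)
    i = 0
    n = len(seq)
    while i < n:
        anc = anc_map[i]
        in_motif = anc in motif_anc
        # deletion starting here (never deleting motif residues)
        if not in_motif and indel_rate > 0 and rng.random() < indel_rate / 2:
            run = int(rng.geometric(geom_p))
            j = i
            while j < n and j - i < run and anc_map[j] not in motif_anc:
                j += 1
            i = j
            continue
        rate = motif_sub_rate if in_motif else sub_rate
        res = int(seq[i])
        if rng.random() < rate:
            res = int(rng.choice(20, p=cond[res]))
        out.append(res)
        out_map.append(anc)
        # insertion after this residue (never between consecutive motif columns)
        next_in_motif = i + 1 < n and anc_map[i + 1] in motif_anc
        if (not (in_motif and next_in_motif)
                and indel_rate > 0 and rng.random() < indel_rate / 2):
            run = int(rng.geometric(geom_p))
            for _ in range(run):
                out.append(int(rng.choice(20, p=background)))
                out_map.append(-1)
        i += 1
    return np.array(out, dtype=np.int8), out_map


def _build_dag(n_functions: int, dag_depth: int) -> tuple[GoDag, list[str]]:
    """Layered molecular-function DAG with one leaf term per function."""
    terms: dict[str, GoTerm] = {
        MF_ROOT: GoTerm(MF_ROOT, "molecular_function", ()),
    }
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"GO:1{counter[0]:06d}"

    n_l1 = max(2, math.ceil(n_functions / 2))
    layer1 = []
    for b in range(n_l1):
        tid = new_id()
        terms[tid] = GoTerm(tid, f"broad activity {b}", (MF_ROOT,))
        layer1.append(tid)
    leaves: list[str] = []
    for f in range(n_functions):
        parent = layer1[f % n_l1]
        depth = 1
        while depth < dag_depth - 1:
            tid = new_id()
            terms[tid] = GoTerm(tid, f"intermediate activity f{f} d{depth + 1}", (parent,))
            parent = tid
            depth += 1
        leaf = new_id()
        parents = [parent]
        terms[leaf] = GoTerm(leaf, f"specific activity {f}", tuple(parents))
        leaves.append(leaf)
    # make the graph a genuine DAG (not a tree): every other leaf gets a
    # second parent at the same depth, which leaves its shortest-path depth
    # unchanged
    for f in range(1, n_functions, 2):
        leaf = leaves[f]
        other_parent = terms[leaves[f - 1]].parent_ids[0]
        t = terms[leaf]
        if other_parent not in t.parent_ids:
            terms[leaf] = GoTerm(t.id, t.name, t.parent_ids + (other_parent,))
    return GoDag(terms, MF_ROOT), leaves


def _cluster_sizes(domains_per_cell: int, clusters_per_cell: int) -> list[int]:
    k = min(clusters_per_cell, domains_per_cell)
    base = domains_per_cell // k
    extra = domains_per_cell % k
    return [base + (1 if i < extra else 0) for i in range(k)]


def generate_world(params: WorldParams) -> SyntheticWorld:
    """Generate a fully specified world; deterministic given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    background = robinson_background()
    cond = blosum_conditional(background)
    dag, leaves = _build_dag(params.n_functions, params.dag_depth)

    fold_ids = [f"f.{i + 1}" for i in range(params.n_folds)]
    cores = {
        fid: rng.choice(20, size=params.fold_core_length, p=background).astype(np.int8)
        for fid in fold_ids
    }
    max_off = params.fold_core_length - params.motif_length
    offsets = {fid: int(rng.integers(10, max(11, max_off - 9))) for fid in fold_ids}
    motifs = {
        go: rng.choice(20, size=params.motif_length, p=background).astype(np.int8)
        for go in leaves
    }

    domains: list[DomainRecord] = []
    truth: dict[str, DomainTruth] = {}
    cluster_members: dict[str, list[str]] = {}
    sizes = _cluster_sizes(params.domains_per_cell, params.clusters_per_cell)
    for fi, fold in enumerate(fold_ids):
        for gi, go in enumerate(leaves):
            # the cell ancestor: the fold core diverged along the function
            # branch (substitutions only, so columns stay aligned across
            # cells of the fold), with the function motif implanted
            core = cores[fold]
            mutate_mask = rng.random(len(core)) < params.divergence_function
            ancestor = core.copy()
            for p in np.nonzero(mutate_mask)[0]:
                ancestor[p] = rng.choice(20, p=cond[ancestor[p]])
            off = offsets[fold]
            ancestor[off:off + params.motif_length] = motifs[go]
            motif_anc = set(range(off, off + params.motif_length))
            anc_map0 = list(range(len(ancestor)))
            for ci, size in enumerate(sizes):
                cluster = f"cl_{fi}_{gi}_{ci}"
                d_founder = params.divergence_cross + float(
                    rng.uniform(-1.0, 1.0)
                ) * params.divergence_cross_spread
                d_founder = min(max(d_founder, 0.0), 0.95)
                founder, f_map = _mutate(
                    ancestor, anc_map0, motif_anc,
                    d_founder,
                    d_founder * params.motif_conservation,
                    params.indel_rate, params.indel_mean_length,
                    rng, cond, background,
                )
                for mi in range(size):
                    member, m_map = _mutate(
                        founder, f_map, motif_anc,
                        params.divergence_within,
                        params.divergence_within * params.motif_conservation,
                        params.indel_rate / 2, params.indel_mean_length,
                        rng, cond, background,
                    )
                    did = f"d_{fi}_{gi}_{ci}_{mi}"
                    domains.append(DomainRecord(
                        domain_id=did,
                        chain_id="",  # filled during chain assembly
                        fold_id=fold,
                        sequence=decode(member),
                        domain_go_ids={go},
                    ))
                    truth[did] = DomainTruth(
                        fold_id=fold,
                        go_ids={go},
                        motif_positions=[
                            p for p, a in enumerate(m_map) if a in motif_anc
                        ],
                        ancestor_map=list(m_map),
                    )
                    cluster_members.setdefault(cluster, []).append(did)

    chains = _assemble_chains(params, rng, domains, truth, cluster_members)
    return SyntheticWorld(
        params=params, dag=dag, domains=domains, chains=chains, truth=truth
    )


def _assemble_chains(
    params: WorldParams,
    rng: np.random.Generator,
    domains: list[DomainRecord],
    truth: dict[str, DomainTruth],
    cluster_members: dict[str, list[str]],
) -> list[ChainRecord]:
    """Wrap domains into chains; a fraction of clusters pair into
    two-domain chains whose chain-level annotation is the union of both
    domains' terms."""
    by_id = {d.domain_id: d for d in domains}
    names = sorted(cluster_members)
    # pair equal-sized clusters from different folds into multidomain chains
    n_multi_clusters = int(round(params.multidomain_fraction * len(names)))
    n_multi_clusters -= n_multi_clusters % 2
    shuffled = list(names)
    rng.shuffle(shuffled)
    paired: list[tuple[str, str]] = []
    used: set[str] = set()
    for a in shuffled:
        if len(paired) * 2 >= n_multi_clusters:
            break
        if a in used:
            continue
        mate = None
        for b in shuffled:
            if b in used or b == a:
                continue
            if (len(cluster_members[a]) == len(cluster_members[b])
                    and by_id[cluster_members[a][0]].fold_id
                    != by_id[cluster_members[b][0]].fold_id):
                mate = b
                break
        if mate is None:
            continue
        used.update((a, mate))
        paired.append((a, mate))

    chains: list[ChainRecord] = []
    for a, b in paired:
        pair_cluster = f"{a}+{b}"
        for da, db in zip(cluster_members[a], cluster_members[b]):
            cid = f"ch_{da}_{db}"
            by_id[da].chain_id = cid
            by_id[db].chain_id = cid
            chains.append(ChainRecord(
                chain_id=cid,
                domain_ids=[da, db],
                chain_go_ids=set(truth[da].go_ids) | set(truth[db].go_ids),
                cluster_id=pair_cluster,
            ))
    for name in names:
        if name in used:
            continue
        for did in cluster_members[name]:
            cid = f"ch_{did}"
            by_id[did].chain_id = cid
            chains.append(ChainRecord(
                chain_id=cid,
                domain_ids=[did],
                chain_go_ids=set(truth[did].go_ids),
                cluster_id=name,
            ))
    chains.sort(key=lambda c: c.chain_id)
    return chains


def make_fragment_artifact(
    world: SyntheticWorld,
    cell: tuple[str, str],
    n_fragments: int = 3,
    companion_fold: str | None = None,
) -> SyntheticWorld:
    """Add fragment chains that confound chain-to-domain annotation transfer.

    Real structure databases contain isolated fragments of multi-domain
    proteins annotated with the *whole protein's* function.  This helper
    adds ``n_fragments`` single-domain chains whose domain belongs to a
    companion fold that does NOT carry the cell's function, yet whose
    chain-level annotation claims it.  Feeding such a world to the fold
    cover forces the companion fold into the cover — the documented failure
    mode of minimal-set-cover annotation transfer.
    """
    fold_id, go_id = cell
    folds = sorted({d.fold_id for d in world.domains})
    if fold_id not in folds:
        raise ValueError(f"unknown cell fold {fold_id}")
    if companion_fold is None:
        others = [f for f in folds if f != fold_id]
        if not others:
            raise ValueError("no companion fold available")
        companion_fold = others[0]
    rng = np.random.default_rng(world.params.seed + 7919)
    background = robinson_background()
    cond = blosum_conditional(background)
    template = next(d for d in world.domains if d.fold_id == companion_fold)
    tseq = encode(template.sequence)
    tmap = list(range(len(tseq)))
    for k in range(n_fragments):
        frag, _ = _mutate(
            tseq, tmap, set(),
            world.params.divergence_within, world.params.divergence_within,
            world.params.indel_rate, world.params.indel_mean_length,
            rng, cond, background,
        )
        did = f"frag_{fold_id}_{go_id}_{k}"
        cid = f"ch_{did}"
        world.domains.append(DomainRecord(
            domain_id=did,
            chain_id=cid,
            fold_id=companion_fold,
            sequence=decode(frag),
            domain_go_ids=set(),
        ))
        world.truth[did] = DomainTruth(
            fold_id=companion_fold, go_ids=set(), motif_positions=[]
        )
        world.chains.append(ChainRecord(
            chain_id=cid,
            domain_ids=[did],
            chain_go_ids={go_id},
            cluster_id=f"frag_{fold_id}_{go_id}_{k}",
        ))
    return world
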