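"""The evaluation protocol: leave-cluster-out, top-hit labelling, ROC.

For each test chain, every training domain from the same sequence-similarity
cluster is removed *before* anything is built; the profile library is
re-derived on the reduced set, and a parallel flat database holding exactly
the same domain sequences (the non-redundant members of the surviving
profiles, each retaining its fold and GO terms) serves as the
single-sequence comparator.  The chain is queried against both resources;
only the top hit of each list is evaluated.

A top hit is labelled correct in function only when its GO term is EXACTLY
one of the terms of the domain its segment actually aligns to — a more
specific (descendant) prediction counts as a failure, and a correct term
matched in the wrong domain counts as a failure.  Which domain a segment
aligns to is decided by local alignment of the segment against each of the
chain's own domain sequences, with a random-score floor and a margin rule.

Pooled labelled top hits are swept into ROC curves (TPR = Tp/(Tp+Fn),
FPR = Fp/(Fp+Tn)) at every distinct score; the sweep score is
-log10(E-value), monotone in each method's ranking score.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .alphabet import encode, load_matrix, robinson_background
from .align import EvalueParams, LocalAlignmentTrace, fit_gumbel
from .annotation import ChainRecord, DomainRecord
from .library import LibraryParams, ProfileLibrary, build_library
from .ontology import GoDag
from .search import Hit, search_library, top_hit

logger = logging.getLogger(__name__)

GO_PROFILE = "go_profile"
SINGLE_SEQUENCE = "single_sequence"

#: score margin the best domain must hold over the runner-up in domain
#: verification; BLOSUM62 is in half-bit units, so 2.0 is one bit
VERIFY_MARGIN = 2.0
VERIFY_N_RANDOM = 20


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else 0.0


@dataclass
class LabeledTopHit:
    test_chain_id: str
    method: str
    hit: Hit | None
    function_correct: bool
    fold_correct: bool
    domain_verified: bool
    verified_domain_id: str | None = None
    go_depth: int | None = None
    roc_score: float = 0.0

    def __post_init__(self) -> None:
        if self.function_correct and not self.domain_verified:
            raise ValueError("a function match in the wrong domain is not a match")


@dataclass
class RocCurve:
    points: list[tuple[float, float]]
    auc: float
    degenerate: str | None = None  # "all_positive" / "all_negative" if forced

    def __post_init__(self) -> None:
        if not self.points or self.points[0] != (0.0, 0.0) or self.points[-1] != (1.0, 1.0):
            raise ValueError("ROC points must run from (0,0) to (1,1)")
        fprs = [p[0] for p in self.points]
        if any(b < a for a, b in zip(fprs, fprs[1:])):
            raise ValueError("FPR must be non-decreasing along the curve")


def exclude_cluster(
    domains: list[DomainRecord],
    chains: list[ChainRecord],
    test_cluster_id: str,
) -> tuple[list[DomainRecord], list[ChainRecord]]:
    """Drop every chain in the test cluster, together with all its domains."""
    kept_chains = [c for c in chains if c.cluster_id != test_cluster_id]
    kept_chain_ids = {c.chain_id for c in kept_chains}
    kept_domains = [d for d in domains if d.chain_id in kept_chain_ids]
    return kept_domains, kept_chains


def flat_database(library: ProfileLibrary,
                  domains_by_id: dict[str, DomainRecord]) -> list[DomainRecord]:
    """The single-sequence comparator database: exactly the domain
    sequences inside the library's profiles, fold/GO labels retained."""
    seen: set[str] = set()
    flat: list[DomainRecord] = []
    for entry in library.entries:
        for mid in entry.member_ids:
            if mid not in seen:
                seen.add(mid)
                flat.append(domains_by_id[mid])
    return flat


def _degenerate_profile(seq: str, submat: np.ndarray) -> np.ndarray:
    """A sequence viewed as a profile: column c scores submat[seq[c], :]."""
    idx = encode(seq)
    return np.ascontiguousarray(submat[idx.astype(np.int64), :])


def calibrate_flat(
    params: LibraryParams,
    typical_target_length: int,
    seed: int,
    n_random: int = 200,
    background: np.ndarray | None = None,
    submat: np.ndarray | None = None,
) -> EvalueParams:
    """Gumbel (lambda, k) for sequence-vs-sequence local scores.

    Fitted from optimal scores of random background query/target pairs;
    E-values against a database then scale linearly with the total database
    length.
    """
    if background is None:
        background = robinson_background()
    if submat is None:
        submat = load_matrix()
    rng = np.random.default_rng(seed)
    scores = np.empty(n_random)
    for i in range(n_random):
        q = rng.choice(20, size=params.calibration_length, p=background).astype(np.int8)
        t = rng.choice(20, size=typical_target_length, p=background).astype(np.int8)
        prof = np.ascontiguousarray(submat[t.astype(np.int64), :])
        scores[i] = _kernels.sw_profile_score(
            q, prof, float(params.gap_open), float(params.gap_extend)
        )
    return fit_gumbel(scores, m=params.calibration_length, n=typical_target_length)


def flat_search(
    query_id: str,
    query_sequence: str,
    flat_domains: list[DomainRecord],
    params: LibraryParams,
    evalue_params: EvalueParams,
    max_evalue: float = 10.0,
    submat: np.ndarray | None = None,
) -> list[Hit]:
    """Smith-Waterman of the query against each flat-database sequence.

    Each hit carries the matched domain's fold and its GO terms (one
    primary term plus the rest as candidates, all evaluated).  E-values use
    the shared sequence-vs-sequence calibration, scaled to the total
    database length.
    """
    if submat is None:
        submat = load_matrix()
    if not flat_domains:
        return []
    q = encode(query_sequence)
    total_len = sum(len(d.sequence) for d in flat_domains)
    hits: list[Hit] = []
    for dom in flat_domains:
        prof = _degenerate_profile(dom.sequence, submat)
        score, qstart, qend, cols = _kernels.sw_profile(
            q, prof, float(params.gap_open), float(params.gap_extend)
        )
        if score <= 0:
            continue
        e = (evalue_params.k * len(query_sequence) * total_len
             * math.exp(-evalue_params.lambda_ * score))
        if e > max_evalue:
            continue
        terms = sorted(dom.domain_go_ids)
        trace = LocalAlignmentTrace(
            query_start=int(qstart),
            query_end=int(qend),
            profile_columns=[None if c < 0 else int(c) for c in cols],
            score=float(score),
        )
        hits.append(Hit(
            query_id=query_id,
            fold_id=dom.fold_id,
            go_id=terms[0] if terms else "",
            trace=trace,
            score=float(score),
            evalue=float(e),
            candidate_go_ids=frozenset(terms),
        ))
    hits.sort(key=Hit.sort_key)
    return hits


def verify_domain(
    hit: Hit,
    test_chain: ChainRecord,
    domains_by_id: dict[str, DomainRecord],
    params: LibraryParams | None = None,
    rng_seed: int = 0,
    margin: float = VERIFY_MARGIN,
    submat: np.ndarray | None = None,
    background: np.ndarray | None = None,
) -> str | None:
    """Which of the chain's own domains does the hit's segment align to?

    The segment is locally aligned against each domain sequence; the best
    domain wins if its score exceeds (a) the score expected against a
    length-matched random sequence plus three standard deviations and
    (b) the runner-up by at least ``margin``.  Returns None when ambiguous
    or insignificant.
    """
    params = params or LibraryParams()
    if submat is None:
        submat = load_matrix()
    if background is None:
        background = robinson_background()
    missing = [d for d in test_chain.domain_ids if d not in domains_by_id]
    if missing:
        raise ValueError(
            f"chain {test_chain.chain_id} lacks domain decomposition: {missing}"
        )
    chain_seq = "".join(domains_by_id[d].sequence for d in test_chain.domain_ids)
    start, end = hit.query_interval
    if not (0 <= start < end <= len(chain_seq)):
        raise ValueError("hit interval outside the chain sequence")
    segment = encode(chain_seq[start:end])
    scores: list[tuple[float, str]] = []
    for did in test_chain.domain_ids:
        prof = _degenerate_profile(domains_by_id[did].sequence, submat)
        s = _kernels.sw_profile_score(
            segment, prof, float(params.gap_open), float(params.gap_extend)
        )
        scores.append((float(s), did))
    scores.sort(key=lambda t: (-t[0], t[1]))
    best_score, best_id = scores[0]
    # random floor: the segment against length-matched random sequences
    rng = np.random.default_rng(rng_seed)
    target_len = len(domains_by_id[best_id].sequence)
    rand_scores = np.empty(VERIFY_N_RANDOM)
    for i in range(VERIFY_N_RANDOM):
        t = rng.choice(20, size=target_len, p=background).astype(np.int8)
        prof = np.ascontiguousarray(submat[t.astype(np.int64), :])
        rand_scores[i] = _kernels.sw_profile_score(
            segment, prof, float(params.gap_open), float(params.gap_extend)
        )
    floor = float(rand_scores.mean() + 3.0 * rand_scores.std())
    if best_score <= floor:
        return None
    if len(scores) > 1 and best_score - scores[1][0] < margin:
        return None
    return best_id


def label_top_hit(
    hit: Hit | None,
    test_chain: ChainRecord,
    domains_by_id: dict[str, DomainRecord],
    dag: GoDag,
    min_eval_depth: int = 2,
    method: str = GO_PROFILE,
    params: LibraryParams | None = None,
    rng_seed: int = 0,
    verified_domain_id: str | None | type(Ellipsis) = Ellipsis,
) -> LabeledTopHit | None:
    """Label one top hit; returns None when it is excluded from evaluation.

    Exclusion happens when there is no hit at all, or when none of the
    hit's GO terms reaches ``min_eval_depth`` (too broad to be evaluated).
    ``verified_domain_id`` may be passed in to reuse an already-computed
    verification.
    """
    if hit is None:
        return None
    eligible = sorted(
        t for t in hit.all_go_ids()
        if t and t in dag and dag.distance_to_root(t) >= min_eval_depth
    )
    if not eligible:
        return None
    if verified_domain_id is Ellipsis:
        verified_domain_id = verify_domain(
            hit, test_chain, domains_by_id, params=params, rng_seed=rng_seed
        )
    verified = verified_domain_id is not None
    fold_correct = False
    function_correct = False
    if verified:
        true_dom = domains_by_id[verified_domain_id]
        fold_correct = true_dom.fold_id == hit.fold_id
        # exact term identity only: an ancestor or descendant of the true
        # term counts as a failure
        function_correct = any(t in true_dom.domain_go_ids for t in eligible)
    go_depth = dag.distance_to_root(hit.go_id) if hit.go_id in dag else None
    e = max(hit.evalue, 1e-300)
    return LabeledTopHit(
        test_chain_id=test_chain.chain_id,
        method=method,
        hit=hit,
        function_correct=function_correct,
        fold_correct=fold_correct,
        domain_verified=verified,
        verified_domain_id=verified_domain_id,
        go_depth=go_depth,
        roc_score=-math.log10(e),
    )


def roc(labeled: list[LabeledTopHit], correctness_field: str = "function_correct") -> RocCurve:
    """Threshold sweep over ``roc_score`` at every distinct score.

    Hits scoring above the threshold are predicted positive; ties collapse
    to a single sweep point.  Raises when either class is empty.
    """
    if correctness_field not in ("function_correct", "fold_correct"):
        raise ValueError(f"unknown correctness field {correctness_field!r}")
    pairs = [(l.roc_score, getattr(l, correctness_field)) for l in labeled]
    n_pos = sum(1 for _, y in pairs if y)
    n_neg = len(pairs) - n_pos
    if n_pos == 0:
        raise ValueError("no positive labels: ROC undefined")
    if n_neg == 0:
        raise ValueError("no negative labels: ROC undefined")
    pairs.sort(key=lambda t: -t[0])
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(pairs):
        j = i
        while j < len(pairs) and pairs[j][0] == pairs[i][0]:
            if pairs[j][1]:
                tp += 1
            else:
                fp += 1
            j += 1
        counts = ConfusionCounts(tp=tp, fn=n_pos - tp, fp=fp, tn=n_neg - fp)
        points.append((counts.fpr, counts.tpr))
        i = j
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return RocCurve(points=points, auc=auc)


def _roc_or_degenerate(labeled: list[LabeledTopHit], field: str) -> RocCurve | None:
    if not labeled:
        return None
    try:
        return roc(labeled, field)
    except ValueError:
        all_pos = all(getattr(l, field) for l in labeled)
        tag = "all_positive" if all_pos else "all_negative"
        logger.warning("ROC degenerate (%s) for %s on %d hits", tag, field, len(labeled))
        return RocCurve(
            points=[(0.0, 0.0), (1.0, 1.0)],
            auc=1.0 if all_pos else 0.0,
            degenerate=tag,
        )


@dataclass
class BenchmarkResult:
    curves: dict[tuple[str, int, str], RocCurve | None]
    labeled: dict[tuple[str, int], list[LabeledTopHit]]
    skipped_chains: list[str] = field(default_factory=list)

    def auc(self, method: str, depth: int, field: str = "function_correct") -> float | None:
        curve = self.curves.get((method, depth, field))
        return curve.auc if curve else None

    def summary(self) -> dict:
        out = {}
        for (method, depth, fieldname), curve in sorted(self.curves.items()):
            key = f"{method}_depth{depth}_{'function' if 'function' in fieldname else 'fold'}"
            out[key] = None if curve is None else round(curve.auc, 4)
        return out


def _stable_seed(seed: int, *parts: str) -> int:
    return zlib.crc32(("|".join([str(seed), *parts])).encode()) & 0x7FFFFFFF


def run_benchmark(
    test_chains: list[ChainRecord],
    domains: list[DomainRecord],
    chains: list[ChainRecord],
    dag: GoDag,
    params: LibraryParams | None = None,
    seed: int = 0,
    depths: tuple[int, ...] = (2, 4),
    max_evalue: float = 10.0,
    aligner=None,
) -> BenchmarkResult:
    """Leave-cluster-out benchmark of profile vs single-sequence search.

    For every test chain: exclude its cluster, rebuild the library and the
    flat database, query the chain against both, evaluate the top hits, and
    pool the labels into per-method ROC curves at each GO-depth filter.
    Fully deterministic given ``seed``.

    ``aligner`` is the binary aligner used for the profile pile-ups
    (default: sequence-based global alignment; pass a structure-derived
    aligner to reproduce a structural-superposition regime).
    """
    if not test_chains:
        raise ValueError("no test chains")
    params = params or LibraryParams()
    domains_by_id = {d.domain_id: d for d in domains}
    submat = load_matrix()
    entry_cache: dict = {}
    typical_len = int(np.median([len(d.sequence) for d in domains])) if domains else 100
    flat_ev = calibrate_flat(params, typical_len, seed=_stable_seed(seed, "flatcal"))

    labeled: dict[tuple[str, int], list[LabeledTopHit]] = {
        (m, d): [] for m in (GO_PROFILE, SINGLE_SEQUENCE) for d in depths
    }
    skipped: list[str] = []
    for chain in test_chains:
        train_domains, train_chains = exclude_cluster(domains, chains, chain.cluster_id)
        library = build_library(
            train_domains, train_chains, dag, params,
            seed=seed, entry_cache=entry_cache,
            **({"aligner": aligner} if aligner is not None else {}),
        )
        flat = flat_database(library, {d.domain_id: d for d in train_domains})
        if not library.entries and not flat:
            logger.warning("chain %s: exclusion empties both databases; skipped",
                           chain.chain_id)
            skipped.append(chain.chain_id)
            continue
        qseq = "".join(domains_by_id[d].sequence for d in chain.domain_ids)
        searches = {
            GO_PROFILE: search_library(chain.chain_id, qseq, library, max_evalue)
            if library.entries else [],
            SINGLE_SEQUENCE: flat_search(
                chain.chain_id, qseq, flat, params, flat_ev, max_evalue
            ),
        }
        for method, hits in searches.items():
            th = top_hit(hits)
            if th is None:
                continue
            verified = verify_domain(
                th, chain, domains_by_id, params=params,
                rng_seed=_stable_seed(seed, chain.chain_id, method),
            )
            for depth in depths:
                rec = label_top_hit(
                    th, chain, domains_by_id, dag,
                    min_eval_depth=depth, method=method, params=params,
                    verified_domain_id=verified,
                )
                if rec is not None:
                    labeled[(method, depth)].append(rec)

    curves: dict[tuple[str, int, str], RocCurve | None] = {}
    for (method, depth), recs in labeled.items():
        for fieldname in ("function_correct", "fold_correct"):
            curves[(method, depth, fieldname)] = _roc_or_degenerate(recs, fieldname)
    return BenchmarkResult(curves=curves, labeled=labeled, skipped_chains=skipped)


def motif_site_recall(
    world,
    params: LibraryParams | None = None,
    seed: int = 0,
    max_entries: int | None = None,
    max_evalue: float = 10.0,
) -> tuple[float, int]:
    """Mean recall of implanted motif positions under hold-one-member-out.

    Every member of every profile entry is queried against a library
    rebuilt without it; the top hit's conserved columns are mapped onto the
    query and compared with the generator's true motif positions.  Returns
    ``(mean recall, number of queries)``.
    """
    from .search import predict_sites

    params = params or LibraryParams()
    aligner = world.structural_aligner()
    dbi = world.domains_by_id()
    cache: dict = {}
    full = build_library(world.domains, world.chains, world.dag, params,
                         aligner=aligner, seed=seed, entry_cache=cache)
    entries = full.entries[:max_entries] if max_entries else full.entries
    recalls: list[float] = []
    for entry in entries:
        for mid in entry.member_ids:
            held_chain = dbi[mid].chain_id
            chains = [c for c in world.chains if c.chain_id != held_chain]
            dropped = {
                d for c in world.chains if c.chain_id == held_chain
                for d in c.domain_ids
            }
            domains = [d for d in world.domains if d.domain_id not in dropped]
            lib = build_library(domains, chains, world.dag, params,
                                aligner=aligner, seed=seed, entry_cache=cache)
            qseq = dbi[mid].sequence
            th = top_hit(search_library(mid, qseq, lib, max_evalue))
            motif = set(world.truth[mid].motif_positions)
            if not motif:
                continue
            if th is None:
                recalls.append(0.0)
                continue
            pred = predict_sites(th, lib.get(*th.entry_ref), qseq)
            recalls.append(len(motif & set(pred.query_positions)) / len(motif))
    return (float(np.mean(recalls)) if recalls else 0.0, len(recalls))


def pick_test_chains(
    chains: list[ChainRecord],
    n: int,
    seed: int = 0,
) -> list[ChainRecord]:
    """One representative chain per cluster (the first with an annotated
    domain), subsampled to ``n`` deterministically."""
    by_cluster: dict[str, ChainRecord] = {}
    for c in sorted(chains, key=lambda c: c.chain_id):
        if c.cluster_id not in by_cluster and c.chain_go_ids:
            by_cluster[c.cluster_id] = c
    reps = [by_cluster[k] for k in sorted(by_cluster)]
    if len(reps) <= n:
        return reps
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reps), size=n, replace=False)
    return [reps[i] for i in sorted(idx)]
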