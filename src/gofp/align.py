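"""Pairwise global and profile-local alignment, with empirical E-values.

The pile-up that builds each profile entry consumes *binary* master-vs-domain
alignments through the :class:`PairwiseAlignment` interface.  The built-in
producer is sequence-based Needleman-Wunsch (BLOSUM62, gap open -11, gap
extend -1); structure-derived binary alignments can be supplied in the same
form to reproduce a structural-superposition regime.

Library searches use :func:`profile_sw`: local Smith-Waterman of a query
sequence against a position-specific scoring matrix, the sequence-vs-profile
analogue of a reverse PSI-BLAST search.  Hit significance follows the
Karlin-Altschul form E = k * m * n * exp(-lambda * S), with (lambda, k)
fitted per profile from the Gumbel distribution of optimal local scores of
random background sequences (gapped alignment statistics have no closed
form, so the parameters are calibrated empirically and deterministically
from a seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .alphabet import GAP, encode, load_matrix, robinson_background

#: Euler-Mascheroni constant (Gumbel mean = mu + gamma / lambda).
EULER_GAMMA = 0.5772156649015329

DEFAULT_GAP_OPEN = -11.0
DEFAULT_GAP_EXTEND = -1.0


@dataclass
class PairwiseAlignment:
    """A gapped pair of sequences; no column may be gap/gap."""

    id_a: str
    id_b: str
    gapped_a: str
    gapped_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise ValueError("aligned rows differ in length")
        for ca, cb in zip(self.gapped_a, self.gapped_b):
            if ca == GAP and cb == GAP:
                raise ValueError("gap/gap column in alignment")

    def ungapped_a(self) -> str:
        return self.gapped_a.replace(GAP, "")

    def ungapped_b(self) -> str:
        return self.gapped_b.replace(GAP, "")


@dataclass
class LocalAlignmentTrace:
    """A local match of a query segment against profile columns.

    ``profile_columns`` is parallel to query positions ``start..end-1``: the
    matched 0-based column index, or None where the query residue is an
    insertion relative to the profile.  Profile columns skipped between two
    matched ones are deletions (gapped in the query).
    """

    query_start: int
    query_end: int
    profile_columns: list[int | None]
    score: float

    @property
    def query_interval(self) -> tuple[int, int]:
        return (self.query_start, self.query_end)

    def matched_pairs(self) -> list[tuple[int, int]]:
        """(query position, profile column) for every matched (non-gap) pair."""
        return [
            (self.query_start + i, c)
            for i, c in enumerate(self.profile_columns)
            if c is not None
        ]

    def column_for_query(self) -> dict[int, int]:
        return dict(self.matched_pairs())

    def query_for_column(self) -> dict[int, int]:
        return {c: p for p, c in self.matched_pairs()}


@dataclass(frozen=True)
class EvalueParams:
    """Gumbel / Karlin-Altschul parameters: E = k * m * n * exp(-lambda * S)."""

    lambda_: float
    k: float
    m: int
    n: int

    def __post_init__(self) -> None:
        if not (self.lambda_ > 0 and self.k > 0 and self.m > 0 and self.n > 0):
            raise ValueError("EvalueParams fields must all be strictly positive")

    def with_query_length(self, m: int) -> "EvalueParams":
        return replace(self, m=m)


def global_align(
    seq_a: str,
    seq_b: str,
    substitution_matrix: np.ndarray | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    id_a: str = "a",
    id_b: str = "b",
) -> PairwiseAlignment:
    """Optimal global alignment with affine gaps (open + L*extend per gap).

    Deterministic tie-break: diagonal preferred over a gap in ``seq_b``,
    preferred over a gap in ``seq_a``.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    if gap_open >= 0 or gap_extend >= 0:
        raise ValueError("gap penalties must be negative")
    sub = substitution_matrix if substitution_matrix is not None else load_matrix()
    a = encode(seq_a)
    b = encode(seq_b)
    score, ops = _kernels.nw_affine(a, b, sub, float(gap_open), float(gap_extend))
    rows_a: list[str] = []
    rows_b: list[str] = []
    i = j = 0
    sa, sb = seq_a.upper(), seq_b.upper()
    for op in ops:
        if op == 0:
            rows_a.append(sa[i])
            rows_b.append(sb[j])
            i += 1
            j += 1
        elif op == 1:
            rows_a.append(sa[i])
            rows_b.append(GAP)
            i += 1
        else:
            rows_a.append(GAP)
            rows_b.append(sb[j])
            j += 1
    return PairwiseAlignment(
        id_a=id_a, id_b=id_b,
        gapped_a="".join(rows_a), gapped_b="".join(rows_b),
        score=float(score),
    )


def percent_identity(aln: PairwiseAlignment, denominator: str = "nongap") -> float:
    """Percent identical columns.

    ``denominator="nongap"`` (default) divides by the number of columns where
    neither row is a gap; ``"shorter"`` divides by the shorter ungapped
    sequence length.  Returns 0 when the denominator is 0.
    """
    ident = nongap = 0
    for ca, cb in zip(aln.gapped_a, aln.gapped_b):
        if ca != GAP and cb != GAP:
            nongap += 1
            if ca == cb:
                ident += 1
    if denominator == "nongap":
        denom = nongap
    elif denominator == "shorter":
        denom = min(len(aln.ungapped_a()), len(aln.ungapped_b()))
    else:
        raise ValueError(f"unknown identity denominator {denominator!r}")
    return 100.0 * ident / denom if denom else 0.0


def _pssm_matrix(pssm) -> np.ndarray:
    """Accept a Pssm object or a raw (n_columns, 20|21) array."""
    if hasattr(pssm, "score_matrix21"):
        return pssm.score_matrix21()
    arr = np.asarray(pssm, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] not in (20, 21):
        raise ValueError("profile matrix must be (n_columns, 20 or 21)")
    if arr.shape[1] == 20:
        arr = np.hstack([arr, np.zeros((arr.shape[0], 1))])
    return np.ascontiguousarray(arr)


def profile_sw(
    query: str,
    pssm,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> LocalAlignmentTrace:
    """Optimal local alignment of a sequence against a profile.

    Matching query residue ``r`` to column ``c`` scores ``pssm.score(c, r)``;
    gaps are affine on both sides.  When no cell scores above zero the empty
    trace (score 0) is returned.
    """
    if not query:
        raise ValueError("empty query")
    mat = _pssm_matrix(pssm)
    if mat.shape[0] < 1:
        raise ValueError("profile has no columns")
    q = encode(query)
    score, qstart, qend, cols = _kernels.sw_profile(
        q, mat, float(gap_open), float(gap_extend)
    )
    profile_columns: list[int | None] = [
        None if c < 0 else int(c) for c in cols
    ]
    return LocalAlignmentTrace(
        query_start=int(qstart),
        query_end=int(qend),
        profile_columns=profile_columns,
        score=float(score),
    )


def profile_sw_score(query_idx: np.ndarray, matrix: np.ndarray,
                     gap_open: float = DEFAULT_GAP_OPEN,
                     gap_extend: float = DEFAULT_GAP_EXTEND) -> float:
    """Score-only fast path on pre-encoded input (used in calibration loops)."""
    return float(
        _kernels.sw_profile_score(query_idx, matrix, float(gap_open), float(gap_extend))
    )


def evalue(score: float, params: EvalueParams) -> float:
    """Expected number of chance hits at or above ``score``."""
    return params.k * params.m * params.n * math.exp(-params.lambda_ * score)


def bit_score_like(score: float, params: EvalueParams) -> float:
    """-log10 of the E-value: the monotone score used for ROC sweeps."""
    e = evalue(score, params)
    return -math.log10(e) if e > 0 else math.inf


def fit_gumbel(scores: np.ndarray, m: int, n: int) -> EvalueParams:
    """Method-of-moments Gumbel fit of optimal-score samples.

    lambda = pi / (sigma * sqrt(6)); the location mu = mean - gamma/lambda
    is absorbed into k so that E(mu) = 1 for one comparison of size m x n.
    """
    scores = np.asarray(scores, dtype=float)
    sigma = float(scores.std())
    if sigma == 0.0:
        raise ValueError(
            "degenerate score distribution (sigma = 0); "
            "use longer or more random sequences"
        )
    lam = math.pi / (sigma * math.sqrt(6.0))
    mu = float(scores.mean()) - EULER_GAMMA / lam
    k = math.exp(lam * mu) / (m * n)
    return EvalueParams(lambda_=lam, k=k, m=m, n=n)


def calibrate_evalue(
    pssm,
    n_random: int = 500,
    length: int = 200,
    background: np.ndarray | None = None,
    rng_seed: int = 0,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> EvalueParams:
    """Fit (lambda, k) from profile scores of random background sequences.

    Deterministic given ``rng_seed``.  At least 100 random sequences are
    required for a usable fit.
    """
    if n_random < 100:
        raise ValueError("n_random must be >= 100 for a stable Gumbel fit")
    if background is None:
        background = robinson_background()
    mat = _pssm_matrix(pssm)
    rng = np.random.default_rng(rng_seed)
    draws = rng.choice(20, size=(n_random, length), p=background).astype(np.int8)
    scores = np.empty(n_random)
    for i in range(n_random):
        scores[i] = _kernels.sw_profile_score(
            draws[i], mat, float(gap_open), float(gap_extend)
        )
    return fit_gumbel(scores, m=length, n=mat.shape[0])
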