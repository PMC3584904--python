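"""Position-specific scoring matrices from master-framed alignments.

A profile column's score for residue ``a`` is the log2-odds of the
pseudocount-regularised column frequency against the background:

    f(c,a) = (n(c,a) + beta * p(a)) / (N(c) + beta)
    score(c,a) = log2(f(c,a) / p(a)),  floored at -10

with a single-component background pseudocount of total weight ``beta``
(default 5).  Gaps contribute nothing to the counts.  Conserved columns —
the functional-site signal carried by each profile entry — are those where
a single residue accounts for at least the conservation threshold (default
95%) of ALL rows, gaps counting in the denominator: a gapped row is
evidence against conservation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA_ORDER, GAP, robinson_background

logger = logging.getLogger(__name__)

SCORE_FLOOR = -10.0


@dataclass
class MultipleAlignment:
    """Master-framed pseudo-multiple alignment (columns = master residues)."""

    master_id: str
    row_ids: list[str]
    rows: list[str]
    discarded_insertions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise ValueError("alignment rows differ in length")
        if widths == {0}:
            raise ValueError("alignment has zero columns")
        if len(self.row_ids) != len(self.rows):
            raise ValueError("row_ids and rows differ in length")
        if self.master_id not in self.row_ids:
            raise ValueError(f"master {self.master_id} is not a row")
        if GAP in self.master_row:
            raise ValueError("master row may not contain gaps")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def master_row(self) -> str:
        return self.rows[self.row_ids.index(self.master_id)]


@dataclass
class Pssm:
    """Per-column log2-odds scores over the 20 canonical residues."""

    scores: np.ndarray           # (n_columns, 20)
    background: np.ndarray       # (20,) strictly positive, sums to 1
    beta: float
    column_counts: np.ndarray    # (n_columns, 20) raw residue counts

    def __post_init__(self) -> None:
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("scores must be (n_columns, 20)")
        if self.scores.shape[0] < 1:
            raise ValueError("PSSM must have at least one column")
        if not np.all(self.background > 0):
            raise ValueError("background must be strictly positive")
        if abs(float(self.background.sum()) - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("PSSM scores must be finite")

    @property
    def n_columns(self) -> int:
        return int(self.scores.shape[0])

    def score(self, column: int, residue: str) -> float:
        if residue == "X":
            return 0.0
        return float(self.scores[column, AA_ORDER.index(residue)])

    def score_matrix21(self) -> np.ndarray:
        """Dense (n_columns, 21) matrix; the X column scores 0."""
        return np.ascontiguousarray(
            np.hstack([self.scores, np.zeros((self.n_columns, 1))])
        )

    def consensus(self, column: int) -> str:
        return AA_ORDER[int(np.argmax(self.column_counts[column]))]


def _count_columns(aln: MultipleAlignment,
                   row_weights: np.ndarray | None = None) -> np.ndarray:
    dtype = np.int64 if row_weights is None else float
    counts = np.zeros((aln.n_columns, 20), dtype=dtype)
    index = {aa: i for i, aa in enumerate(AA_ORDER)}
    for r, row in enumerate(aln.rows):
        w = 1 if row_weights is None else row_weights[r]
        for c, ch in enumerate(row):
            i = index.get(ch)
            if i is not None:  # gaps and X contribute nothing
                counts[c, i] += w
    return counts


def henikoff_weights(aln: MultipleAlignment) -> np.ndarray:
    """Position-based sequence weights (Henikoff & Henikoff).

    Each column distributes one unit of weight equally over the distinct
    residues present, then equally over the rows carrying each residue;
    row weights are the column sums, normalised to sum to the number of
    rows (so unweighted counting corresponds to all-equal weights of 1).
    """
    index = {aa: i for i, aa in enumerate(AA_ORDER)}
    w = np.zeros(aln.n_rows)
    for c in range(aln.n_columns):
        col = [row[c] for row in aln.rows]
        present: dict[str, int] = {}
        for ch in col:
            if ch in index:
                present[ch] = present.get(ch, 0) + 1
        k = len(present)
        if k == 0:
            continue
        for r, ch in enumerate(col):
            if ch in present:
                w[r] += 1.0 / (k * present[ch])
    if w.sum() == 0:
        return np.ones(aln.n_rows)
    return w * (aln.n_rows / w.sum())


def build_pssm(
    aln: MultipleAlignment,
    background: np.ndarray | None = None,
    beta: float = 5.0,
    effective_count: float | None = None,
    sequence_weighting: bool = False,
) -> Pssm:
    """Estimate the PSSM of an alignment with background pseudocounts.

    ``beta = 0`` is allowed; unobserved residues are then floored at -10
    rather than -inf.  All-gap columns get all-zero scores with a warning.
    ``sequence_weighting`` turns on Henikoff position-based row weights
    (off by default), which damp the influence of over-represented rows.

    With ``effective_count`` set, observed column counts are renormalised
    to that fixed effective number of observations before the pseudocounts
    are applied.  This puts profiles built from different numbers of
    sequences on the same score scale: otherwise a profile with more rows
    is systematically more generous to any related query than a profile
    with fewer, simply because its observed counts outweigh the prior more.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if background is None:
        background = robinson_background()
    if aln.n_columns == 0:
        raise ValueError("alignment has zero columns")
    weights = henikoff_weights(aln) if sequence_weighting else None
    counts = _count_columns(aln, weights)
    totals = counts.sum(axis=1, keepdims=True).astype(float)
    weighted = counts.astype(float)
    wtotals = totals.copy()
    if effective_count is not None:
        if effective_count <= 0:
            raise ValueError("effective_count must be positive")
        nonzero = totals[:, 0] > 0
        weighted[nonzero] = (
            counts[nonzero] / totals[nonzero] * effective_count
        )
        wtotals[nonzero] = effective_count
    scores = np.zeros((aln.n_columns, 20))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # log2(0) handled by the floor below
        freq = (weighted + beta * background[None, :]) / (wtotals + beta)
        scores = np.log2(freq / background[None, :])
    scores = np.maximum(scores, SCORE_FLOOR)
    empty = totals[:, 0] == 0
    if np.any(empty):
        logger.warning("%d all-gap column(s): scores set to 0", int(empty.sum()))
        scores[empty] = 0.0
    scores[~np.isfinite(scores)] = SCORE_FLOOR
    audit_counts = counts if weights is None else _count_columns(aln)
    return Pssm(
        scores=scores,
        background=np.asarray(background, dtype=float),
        beta=float(beta),
        column_counts=audit_counts,
    )


def conserved_columns(aln: MultipleAlignment, threshold: float = 0.95) -> set[int]:
    """Columns where one residue reaches >= threshold of ALL rows.

    The comparison is inclusive (19/20 passes 0.95); gaps count in the
    denominator but never in the numerator.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    counts = _count_columns(aln)
    frac = counts.max(axis=1) / aln.n_rows
    return {int(c) for c in np.nonzero(frac >= threshold - 1e-12)[0]}


def conservation_fraction(aln: MultipleAlignment, column: int) -> float:
    """Fraction of rows carrying the column's most frequent residue."""
    counts = _count_columns(aln)
    return float(counts[column].max() / aln.n_rows)


def pssm_to_tsv(pssm: Pssm) -> str:
    """Serialize scores as integer-scaled (x100) TSV; bit-exact round trip."""
    lines = ["\t".join(["col"] + list(AA_ORDER))]
    scaled = np.rint(pssm.scores * 100).astype(np.int64)
    for c in range(pssm.n_columns):
        lines.append("\t".join([str(c)] + [str(int(v)) for v in scaled[c]]))
    return "\n".join(lines) + "\n"


def pssm_sidecar(pssm: Pssm, **extra) -> str:
    """JSON sidecar with background, beta, counts and caller metadata."""
    payload = {
        "beta": pssm.beta,
        "background": [float(x) for x in pssm.background],
        "column_counts": pssm.column_counts.tolist(),
        **extra,
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def pssm_from_tsv(tsv_text: str, sidecar_json: str) -> Pssm:
    meta = json.loads(sidecar_json)
    rows = [ln.split("\t") for ln in tsv_text.strip().split("\n")]
    header = rows[0]
    if header[1:] != list(AA_ORDER):
        raise ValueError("unexpected residue order in PSSM TSV")
    scores = np.array([[int(v) for v in r[1:]] for r in rows[1:]], dtype=float) / 100.0
    return Pssm(
        scores=scores,
        background=np.array(meta["background"], dtype=float),
        beta=float(meta["beta"]),
        column_counts=np.array(meta["column_counts"], dtype=np.int64),
    )
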