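"""Residue alphabet, background frequencies and substitution matrices.

All sequence code in the package works on integer-encoded sequences over the
20 canonical amino acids (indices 0-19, in ``AA_ORDER`` order) plus ``X``
(index 20) for unknown residues.  Substitution matrices are exposed as dense
21 x 21 float arrays in that encoding.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
X_INDEX = 20
ALPHABET = AA_ORDER + "X"
GAP = "-"

_AA_TO_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

# Robinson & Robinson (1991) amino-acid background frequencies, the standard
# background used by BLAST-family tools; normalised to sum exactly to 1.
_ROBINSON = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}


def robinson_background() -> np.ndarray:
    """Robinson-Robinson background frequencies over ``AA_ORDER`` (sums to 1)."""
    bg = np.array([_ROBINSON[a] for a in AA_ORDER], dtype=float)
    return bg / bg.sum()


def uniform_background() -> np.ndarray:
    """Uniform 1/20 background, handy for analytically tractable tests."""
    return np.full(20, 1.0 / 20.0)


def encode(sequence: str) -> np.ndarray:
    """Encode a residue string to int8 indices; raises on non-alphabet symbols."""
    seq = sequence.upper()
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq):
        try:
            out[i] = _AA_TO_INDEX[ch]
        except KeyError:
            raise ValueError(
                f"non-alphabet residue {ch!r} at position {i} "
                f"(allowed: {ALPHABET})"
            ) from None
    return out


def decode(indices: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in indices)


def load_matrix(name_or_path: str = "BLOSUM62") -> np.ndarray:
    """Load a substitution matrix as a dense 21x21 array.

    ``name_or_path`` is either the name of a matrix bundled with Biopython
    (e.g. ``"BLOSUM62"``) or a path to a matrix file in NCBI text format.
    """
    try:
        arr = substitution_matrices.load(name_or_path)
    except FileNotFoundError:
        arr = substitution_matrices.read(name_or_path)
    out = np.zeros((21, 21), dtype=np.float64)
    alpha = arr.alphabet
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            if a in alpha and b in alpha:
                out[i, j] = arr[a, b]
    return out


def blosum_conditional(background: np.ndarray | None = None) -> np.ndarray:
    """Substitution-target distribution implied by BLOSUM62.

    Returns a 20x20 row-stochastic matrix ``P[a, b]`` = probability that a
    substitution of residue ``a`` produces residue ``b`` (diagonal zeroed:
    given that a site mutates, it changes residue).  Derived from the BLOSUM
    log-odds via ``q(a,b) ~ p(a) p(b) 2^(s(a,b)/2)`` (half-bit scaling), so
    simulated substitutions prefer biochemically conservative exchanges the
    way real divergent homologs do.
    """
    if background is None:
        background = robinson_background()
    s = load_matrix("BLOSUM62")[:20, :20]
    joint = background[:, None] * background[None, :] * np.exp2(s / 2.0)
    np.fill_diagonal(joint, 0.0)
    cond = joint / joint.sum(axis=1, keepdims=True)
    return cond
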