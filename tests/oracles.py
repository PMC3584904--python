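"""Independent brute-force oracles used by the test suite.

These deliberately avoid dynamic programming and share no code with the
package: alignments are enumerated as monotone matchings (sets of matched
residue pairs with strictly increasing coordinates), which covers every
alignment because maximal gap runs between consecutive matches are scored
as independent affine gaps; hitting sets are enumerated over all subsets.
"""

from __future__ import annotations

import itertools
from math import inf


def _gap_cost(length: int, gap_open: float, gap_extend: float) -> float:
    return gap_open + length * gap_extend if length > 0 else 0.0


def brute_force_global(a, b, sub, gap_open, gap_extend):
    """Optimal global affine-gap score by enumerating all monotone matchings.

    ``a``/``b`` are index sequences, ``sub`` a matrix; a gap of length L
    costs gap_open + L*gap_extend.
    """
    n, m = len(a), len(b)
    best = -inf
    for k in range(0, min(n, m) + 1):
        for qi in itertools.combinations(range(n), k):
            for pj in itertools.combinations(range(m), k):
                s = sum(sub[a[i], b[j]] for i, j in zip(qi, pj))
                prev_i, prev_j = -1, -1
                for i, j in zip(qi, pj):
                    s += _gap_cost(i - prev_i - 1, gap_open, gap_extend)
                    s += _gap_cost(j - prev_j - 1, gap_open, gap_extend)
                    prev_i, prev_j = i, j
                s += _gap_cost(n - 1 - prev_i, gap_open, gap_extend)
                s += _gap_cost(m - 1 - prev_j, gap_open, gap_extend)
                best = max(best, s)
    return best


def brute_force_local(q, pssm, gap_open, gap_extend):
    """Optimal local score of a sequence against a profile matrix
    (non-empty matchings, no end-gap costs; floor 0)."""
    n = len(q)
    C = pssm.shape[0]
    best = 0.0
    for k in range(1, min(n, C) + 1):
        for qi in itertools.combinations(range(n), k):
            for cj in itertools.combinations(range(C), k):
                s = sum(pssm[j, q[i]] for i, j in zip(qi, cj))
                for (i1, j1), (i2, j2) in zip(zip(qi, cj), zip(qi[1:], cj[1:])):
                    s += _gap_cost(i2 - i1 - 1, gap_open, gap_extend)
                    s += _gap_cost(j2 - j1 - 1, gap_open, gap_extend)
                best = max(best, s)
    return best


def brute_force_hitting_set(sets):
    """Smallest hitting set; lexicographically first among minima."""
    universe = sorted(set().union(*sets))
    for size in range(1, len(universe) + 1):
        for cand in itertools.combinations(universe, size):
            cs = set(cand)
            if all(cs & s for s in sets):
                return cs
    raise AssertionError("universe must hit everything")


def all_path_lengths_to_root(parents: dict[str, tuple[str, ...]], root: str, node: str):
    """Every directed path length from node to root, by exhaustive walk."""
    if node == root:
        return [0]
    lengths = []
    for p in parents[node]:
        lengths.extend(1 + l for l in all_path_lengths_to_root(parents, root, p))
    return lengths
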