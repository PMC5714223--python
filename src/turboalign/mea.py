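"""Per-sequence structure prediction from final pair probabilities.

Maximum expected accuracy: find the non-crossing structure maximizing
sum over pairs of 2*P(i,j) plus sum over single-stranded positions of the
unpaired probability P(i), by a Nussinov-style interval dynamic program.
A simpler probability-threshold mode keeps every pair above a cutoff,
resolving partner conflicts greedily by descending probability.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .io_formats import SecondaryStructure
from .partition import PairProbabilityMatrix, unpaired_probabilities

DEFAULT_THRESHOLD = 0.5


@njit(cache=True)
def _mea_tables(p, q):
    n = p.shape[0]
    w = np.zeros((n + 2, n + 2))
    cnt = np.zeros((n + 2, n + 2), dtype=np.int64)
    for span in range(0, n):
        for i in range(0, n - span):
            j = i + span
            best = q[i] + w[i + 1, j]
            bc = cnt[i + 1, j]
            for k in range(i + 1, j + 1):
                if p[i, k] > 0.0:
                    s = 2.0 * p[i, k] + w[i + 1, k - 1] + w[k + 1, j]
                    c = 1 + cnt[i + 1, k - 1] + cnt[k + 1, j]
                    if s > best or (s == best and c < bc):
                        best = s
                        bc = c
            w[i, j] = best
            cnt[i, j] = bc
    return w, cnt


def mea_structure(p: PairProbabilityMatrix) -> SecondaryStructure:
    """The maximum expected accuracy structure.

    Ties are broken deterministically, preferring fewer pairs and then the
    lexicographically smallest pair list (the unpaired option is taken
    first, then partners in ascending order).
    """
    q = unpaired_probabilities(p)
    w, cnt = _mea_tables(p.p, q)
    n = p.n
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i > j:
            continue
        # replay the DP choice with the same preference order
        best = q[i] + w[i + 1, j]
        bc = cnt[i + 1, j]
        choice = -1
        for k in range(i + 1, j + 1):
            if p.p[i, k] > 0.0:
                s = 2.0 * p.p[i, k] + w[i + 1, k - 1] + w[k + 1, j]
                c = 1 + cnt[i + 1, k - 1] + cnt[k + 1, j]
                if s > best or (s == best and c < bc):
                    best = s
                    bc = c
                    choice = k
        if choice < 0:
            stack.append((i + 1, j))
        else:
            pairs.append((i + 1, choice + 1))
            stack.append((i + 1, choice - 1))
            stack.append((choice + 1, j))
    return SecondaryStructure(n, frozenset(pairs))


def mea_objective(p: PairProbabilityMatrix, s: SecondaryStructure) -> float:
    """Expected-accuracy objective of a given structure under `p`."""
    q = unpaired_probabilities(p)
    paired = set()
    total = 0.0
    for i, j in s.pairs:
        total += 2.0 * p.p[i - 1, j - 1]
        paired.add(i - 1)
        paired.add(j - 1)
    total += sum(q[i] for i in range(p.n) if i not in paired)
    return total


def threshold_structure(p: PairProbabilityMatrix,
                        t: float = DEFAULT_THRESHOLD) -> SecondaryStructure:
    """All pairs with P(i, j) > t, conflicts resolved greedily by descending
    probability (ties by smallest indices).  For t >= 0.5 the result is
    conflict-free by construction.  Crossing pairs are permitted (CT output
    only; the dot-bracket writer rejects them)."""
    if not (0 < t <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    cand = [(-p.p[i, j], i, j) for i, j in zip(*np.nonzero(p.p > t))]
    cand.sort()
    used: set[int] = set()
    pairs = []
    for negp, i, j in cand:
        if i not in used and j not in used:
            pairs.append((int(i) + 1, int(j) + 1))
            used.add(i)
            used.add(j)
    return SecondaryStructure(p.n, frozenset(pairs))
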