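"""Final multiple alignment.

The aligned-state posteriors of every sequence pair are first re-estimated
by a probabilistic consistency transformation -- averaging the two-step
alignment through every sequence of the set (each endpoint contributes
itself with an identity self-posterior).  A guide tree is then built by
greedy agglomeration on an expected-accuracy similarity, and profiles are
progressively aligned along the tree with a sum-of-pairs dynamic program
over the transformed posteriors (gap score 0; once a gap, always a gap).
The transformation is applied once, and no post-hoc refinement pass is run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Union

import numpy as np

from .io_formats import GAP, MultipleAlignment, SequenceSet
from .pair_hmm import mea_decode

if TYPE_CHECKING:  # pragma: no cover
    from .engine import TurboState

#: entries below this are dropped from the intermediary matrices before the
#: consistency matrix products (the endpoint identity terms stay exact)
CONSISTENCY_FLOOR = 1e-3

PairKey = tuple[int, int]


@dataclass(frozen=True)
class GuideTreeNode:
    """Binary merge node; leaves are sequence indices."""

    left: Union[int, "GuideTreeNode"]
    right: Union[int, "GuideTreeNode"]
    score: float

    def leaves(self) -> list[int]:
        out = []
        for child in (self.left, self.right):
            if isinstance(child, GuideTreeNode):
                out.extend(child.leaves())
            else:
                out.append(child)
        return out


@dataclass(frozen=True)
class GuideTree:
    root: Union[int, GuideTreeNode]
    merge_scores: tuple[float, ...]


def _get(aligned: Mapping[PairKey, np.ndarray], m: int, n: int) -> np.ndarray:
    if (m, n) in aligned:
        return aligned[(m, n)]
    return aligned[(n, m)].T


def consistency_transform(
        aligned: Mapping[PairKey, np.ndarray],
        seqs: SequenceSet,
        floor: float = CONSISTENCY_FLOOR) -> dict[PairKey, np.ndarray]:
    """One round of the probabilistic consistency transformation.

    For each pair (m, n), averages A_mo @ A_on over every sequence o of the
    set, with A_mm taken as the identity, so the o = m and o = n terms
    reproduce the input matrix exactly and the transform is the identity for
    a two-sequence set.  Third-sequence terms are sparsified at `floor`
    before the products.
    """
    H = seqs.H
    for m in range(H):
        for n in range(m + 1, H):
            if (m, n) not in aligned and (n, m) not in aligned:
                raise ValueError(f"missing aligned-posterior matrix for pair ({m},{n})")
    sparse = {}
    for key, mat in aligned.items():
        sparse[key] = np.where(mat >= floor, mat, 0.0)
    out: dict[PairKey, np.ndarray] = {}
    for m in range(H):
        for n in range(m + 1, H):
            a_mn = _get(aligned, m, n)
            acc = 2.0 * a_mn
            for o in range(H):
                if o in (m, n):
                    continue
                acc = acc + _get(sparse, m, o) @ _get(sparse, o, n)
            out[(m, n)] = np.clip(acc / H, 0.0, 1.0)
    return out


def _expected_accuracy_similarity(transformed: Mapping[PairKey, np.ndarray],
                                  seqs: SequenceSet) -> np.ndarray:
    H = seqs.H
    sim = np.zeros((H, H))
    for m in range(H):
        for n in range(m + 1, H):
            _, score = mea_decode(_get(transformed, m, n))
            sim[m, n] = sim[n, m] = score / min(seqs[m].length, seqs[n].length)
    return sim


def build_guide_tree(transformed: Mapping[PairKey, np.ndarray],
                     seqs: SequenceSet) -> GuideTree:
    """Greedy agglomeration on expected-accuracy similarity.

    Cluster similarity is the size-weighted average of member pairs (UPGMA
    linkage), which keeps merge scores non-increasing; ties break on the
    smallest member indices.
    """
    H = seqs.H
    if H < 2:
        raise ValueError("a guide tree needs at least two sequences")
    sim = _expected_accuracy_similarity(transformed, seqs)
    clusters: dict[int, Union[int, GuideTreeNode]] = {m: m for m in range(H)}
    members: dict[int, list[int]] = {m: [m] for m in range(H)}
    merge_scores = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                s = np.mean([sim[x, y] for x in members[a] for y in members[b]])
                if best is None or s > best[0] + 1e-15:
                    best = (s, a, b)
        s, a, b = best
        clusters[a] = GuideTreeNode(clusters[a], clusters[b], float(s))
        members[a] = members[a] + members[b]
        del clusters[b], members[b]
        merge_scores.append(float(s))
    root = clusters[min(clusters)]
    return GuideTree(root, tuple(merge_scores))


# ---------------------------------------------------------------------------
# progressive profile alignment

def _merge_profiles(pos_a: np.ndarray, ids_a: list[int],
                    pos_b: np.ndarray, ids_b: list[int],
                    transformed: Mapping[PairKey, np.ndarray],
                    seqs: SequenceSet) -> tuple[np.ndarray, list[int]]:
    """Profile-profile Needleman-Wunsch on summed cross-pair posteriors.

    `pos_*` are (n_seqs, n_cols) int arrays of 0-based residue positions,
    -1 for gaps.  Column pairs score the sum of P'(i, k) over all cross
    sequence pairs with both residues present; gaps score 0.  Existing
    columns are never split (once a gap, always a gap).
    """
    na, nb = pos_a.shape[1], pos_b.shape[1]
    score = np.zeros((na, nb))
    for ai, s in enumerate(ids_a):
        for bi, t in enumerate(ids_b):
            if s < t:
                mat = transformed[(s, t)]
            else:
                mat = transformed[(t, s)].T
            pad = np.zeros((mat.shape[0] + 1, mat.shape[1] + 1))
            pad[:-1, :-1] = mat
            # -1 gap positions index the zero pad row/column
            score += pad[np.ix_(pos_a[ai], pos_b[bi])]
    dp = np.zeros((na + 1, nb + 1))
    for i in range(1, na + 1):
        for k in range(1, nb + 1):
            best = dp[i - 1, k - 1] + score[i - 1, k - 1]
            if dp[i - 1, k] > best:
                best = dp[i - 1, k]
            if dp[i, k - 1] > best:
                best = dp[i, k - 1]
            dp[i, k] = best
    # traceback: prefer match, then a column from the first profile
    cols: list[tuple[int, int]] = []  # (col in a or -1, col in b or -1)
    i, k = na, nb
    while i > 0 or k > 0:
        if i > 0 and k > 0 and dp[i, k] == dp[i - 1, k - 1] + score[i - 1, k - 1]:
            cols.append((i - 1, k - 1))
            i -= 1
            k -= 1
        elif i > 0 and dp[i, k] == dp[i - 1, k]:
            cols.append((i - 1, -1))
            i -= 1
        else:
            cols.append((-1, k - 1))
            k -= 1
    cols.reverse()
    merged = np.full((len(ids_a) + len(ids_b), len(cols)), -1, dtype=np.int64)
    for c, (ca, cb) in enumerate(cols):
        if ca >= 0:
            merged[:len(ids_a), c] = pos_a[:, ca]
        if cb >= 0:
            merged[len(ids_a):, c] = pos_b[:, cb]
    return merged, ids_a + ids_b


def _align_node(node, transformed, seqs) -> tuple[np.ndarray, list[int]]:
    if isinstance(node, int):
        n = seqs[node].length
        return np.arange(n, dtype=np.int64).reshape(1, n), [node]
    pos_a, ids_a = _align_node(node.left, transformed, seqs)
    pos_b, ids_b = _align_node(node.right, transformed, seqs)
    return _merge_profiles(pos_a, ids_a, pos_b, ids_b, transformed, seqs)


def progressive_align(tree: GuideTree,
                      transformed: Mapping[PairKey, np.ndarray],
                      seqs: SequenceSet) -> MultipleAlignment:
    """Align profiles along the guide tree; rows returned in input order."""
    pos, ids = _align_node(tree.root, transformed, seqs)
    order = np.argsort(ids, kind="stable")
    rows = []
    for r in order:
        m = ids[r]
        res = seqs[m].residues
        rows.append((seqs[m].id,
                     "".join(res[p] if p >= 0 else GAP for p in pos[r])))
    return MultipleAlignment(tuple(rows))


def compute_msa(state: "TurboState", seqs: SequenceSet) -> MultipleAlignment:
    """Consistency transform -> guide tree -> progressive alignment."""
    if seqs.H < 2:
        raise ValueError("a multiple alignment needs at least two sequences")
    aligned = {key: post.aligned for key, post in state.posteriors.items()}
    transformed = consistency_transform(aligned, seqs)
    if seqs.H == 2:
        tree = GuideTree(GuideTreeNode(0, 1, 1.0), (1.0,))
    else:
        tree = build_guide_tree(transformed, seqs)
    return progressive_align(tree, transformed, seqs)
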