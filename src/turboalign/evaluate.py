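"""Accuracy metrics for alignments and structures.

Alignment scoring compares aligned residue pairs (two different sequences,
same column, both residues present) by exact column co-membership.
Structure scoring compares base pairs with the one-position slippage rule:
a predicted pair (i, j) is correct if (i, j), (i+-1, j) or (i, j+-1) is in
the reference, with each reference pair creditable at most once (predicted
pairs are matched greedily in sorted order, exact match tried first).
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import GAP, MultipleAlignment, SecondaryStructure


@dataclass(frozen=True)
class ScorePair:
    """Sensitivity = TP / reference positives, PPV = TP / predicted
    positives; an empty denominator scores 0 and raises the flag."""

    sensitivity: float
    ppv: float
    tp: int
    ref_positives: int
    pred_positives: int
    undefined: bool = False

    @classmethod
    def from_counts(cls, tp: int, refp: int, predp: int) -> "ScorePair":
        undefined = refp == 0 or predp == 0
        return cls(tp / refp if refp else 0.0,
                   tp / predp if predp else 0.0,
                   tp, refp, predp, undefined)


def _aligned_pairs(msa: MultipleAlignment) -> set[tuple[str, int, str, int]]:
    """All (id1, pos1, id2, pos2) residue pairs sharing a column, 1-based,
    ids in the row order of the alignment."""
    pairs = set()
    counters = {sid: 0 for sid, _ in msa.rows}
    for c in range(msa.columns):
        present = []
        for sid, gapped in msa.rows:
            if gapped[c] != GAP:
                counters[sid] += 1
                present.append((sid, counters[sid]))
        for a in range(len(present)):
            for b in range(a + 1, len(present)):
                pairs.add(present[a] + present[b])
    return pairs


def alignment_score(pred: MultipleAlignment,
                    ref: MultipleAlignment) -> ScorePair:
    """Exact aligned-residue-pair agreement between two alignments of the
    same sequences (no slippage for alignment columns)."""
    if set(pred.ids) != set(ref.ids):
        raise ValueError("alignments cover different sequence ids")
    for sid in pred.ids:
        if pred.degapped(sid) != ref.degapped(sid):
            raise ValueError(f"degapped sequences differ for id {sid!r}")
    # canonicalize pair orientation on the reference row order
    order = {sid: r for r, sid in enumerate(ref.ids)}

    def orient(pairs):
        return {(p if order[p[0]] < order[p[2]] else (p[2], p[3], p[0], p[1]))
                for p in pairs}

    pset = orient(_aligned_pairs(pred))
    rset = orient(_aligned_pairs(ref))
    return ScorePair.from_counts(len(pset & rset), len(rset), len(pset))


def structure_score(pred: SecondaryStructure,
                    ref: SecondaryStructure) -> ScorePair:
    """Base-pair agreement with the one-position slippage rule."""
    if pred.length != ref.length:
        raise ValueError("structures have different lengths")
    available = set(ref.pairs)
    tp = 0
    for i, j in sorted(pred.pairs):
        for cand in ((i, j), (i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
            if cand in available:
                available.remove(cand)
                tp += 1
                break
    return ScorePair.from_counts(tp, len(ref.pairs), len(pred.pairs))
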