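"""Shared test utilities: random instances and independent brute-force oracles.

The oracles here deliberately avoid the implementation's dynamic programs:
the HMM oracle enumerates complete alignment paths, the folding oracle is
`enumerate_structures_oracle` (itself exhaustive enumeration), and the MEA
oracle scores every non-crossing structure directly.
"""

from __future__ import annotations

import numpy as np

from turboalign.io_formats import RnaSequence, encode
from turboalign.pair_hmm import HmmParameters
from turboalign.partition import (EnergyModel, PairProbabilityMatrix,
                                  _enumerate_pairsets, unpaired_probabilities)

BASES = "ACGU"


def random_rna(rng: np.random.Generator, n: int, sid: str = "s") -> RnaSequence:
    return RnaSequence(sid, "".join(BASES[i] for i in rng.integers(0, 4, n)))


def random_hmm_params(rng: np.random.Generator) -> HmmParameters:
    t = rng.uniform(0.05, 1.0, (3, 3))
    t /= t.sum(axis=1, keepdims=True)
    ep = rng.uniform(0.01, 1.0, (4, 4))
    ep /= ep.sum()
    es = rng.uniform(0.01, 1.0, 4)
    es /= es.sum()
    return HmmParameters(t, ep, es)


def random_energy_model(rng: np.random.Generator,
                        min_hairpin: int | None = None) -> EnergyModel:
    return EnergyModel(
        pair_weights={
            "GC": float(rng.uniform(1, 3)), "CG": float(rng.uniform(1, 3)),
            "AU": float(rng.uniform(0.5, 2)), "UA": float(rng.uniform(0.5, 2)),
            "GU": float(rng.uniform(0.5, 1.5)), "UG": float(rng.uniform(0.5, 1.5)),
        },
        stack_scale=float(rng.uniform(1, 3)),
        hairpin_base=float(rng.uniform(0.01, 0.5)),
        hairpin_decay=float(rng.uniform(0.0, 0.2)),
        internal_base=float(rng.uniform(0.01, 0.3)),
        internal_decay=float(rng.uniform(0.0, 0.3)),
        bulge_base=float(rng.uniform(0.01, 0.3)),
        bulge_decay=float(rng.uniform(0.0, 0.4)),
        mb_closing=float(rng.uniform(0.01, 0.2)),
        mb_branch=float(rng.uniform(0.1, 0.8)),
        mb_unpaired=float(rng.uniform(0.5, 1.0)),
        min_hairpin=int(rng.integers(1, 4)) if min_hairpin is None else min_hairpin,
    )


def random_pair_matrix(rng: np.random.Generator, n: int) -> PairProbabilityMatrix:
    """A valid strictly-upper-triangular matrix with total involvement <= 1."""
    p = np.triu(rng.uniform(0, 1, (n, n)), k=2)
    for _ in range(100):
        inv = p.sum(axis=0) + p.sum(axis=1)
        mx = inv.max()
        if mx <= 1.0:
            break
        p /= mx * 1.01
    return PairProbabilityMatrix(n, p)


def hmm_path_enumeration(x: RnaSequence, y: RnaSequence, params: HmmParameters,
                         rho: np.ndarray | None = None):
    """Exhaustive enumeration of every monotone alignment path.

    Each path is a sequence of ALN/INS1/INS2 moves from (0,0) to (N1,N2),
    weighted by transition/emission (and rho on ALN moves) products; the
    chain starts in ALN.  Returns (coincidence, aligned) posterior matrices
    over cells with i, k >= 1.
    """
    xs, ys = encode(x.residues), encode(y.residues)
    n1, n2 = len(xs), len(ys)
    if rho is None:
        rho = np.ones((n1, n2))
    t, ep, es = params.transition, params.emission_pair, params.emission_single
    mass = np.zeros((3, n1, n2))
    z = 0.0

    def rec(i, k, state, w, visited):
        nonlocal z
        if i == n1 and k == n2:
            z += w
            for ii, kk, s in visited:
                if ii >= 1 and kk >= 1:
                    mass[s, ii - 1, kk - 1] += w
            return
        if i < n1 and k < n2:
            rec(i + 1, k + 1, 0, w * t[state, 0] * ep[xs[i], ys[k]] * rho[i, k],
                visited + [(i + 1, k + 1, 0)])
        if i < n1:
            rec(i + 1, k, 1, w * t[state, 1] * es[xs[i]],
                visited + [(i + 1, k, 1)])
        if k < n2:
            rec(i, k + 1, 2, w * t[state, 2] * es[ys[k]],
                visited + [(i, k + 1, 2)])

    rec(0, 0, 0, 1.0, [])
    return mass.sum(axis=0) / z, mass[0] / z


def mea_brute_force(ppm: PairProbabilityMatrix) -> float:
    """Best expected-accuracy objective over all non-crossing structures."""
    q = unpaired_probabilities(ppm)
    best = -np.inf
    for pairs in _enumerate_pairsets(ppm.p > 0, 0):
        paired = {i for ij in pairs for i in ij}
        obj = sum(2.0 * ppm.p[i, j] for i, j in pairs)
        obj += sum(q[i] for i in range(ppm.n) if i not in paired)
        best = max(best, obj)
    return best
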