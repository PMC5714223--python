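"""The two information bridges between folding and alignment.

Structure -> alignment: per-position pairing-state profiles (downstream
paired, upstream paired, unpaired) summarize a sequence's base-pair
probability matrix, and a structural match score between two positions
rewards agreement of those states.  The match score feeds the pair HMM as a
prior.

Alignment + structure -> structure: the base-pairing proclivity maps one
sequence's pair probabilities onto another through the posterior
co-incidence matrices, and the extrinsic matrix is the identity-weighted,
max-normalized sum of proclivities from all homologs.  The extrinsic matrix
feeds the partition function as a pseudo-free-energy bonus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .pair_hmm import CoincidencePosteriors
from .partition import PairProbabilityMatrix

DEFAULT_COINCIDENCE_CUTOFF = 0.01

_TOL = 1e-9


@dataclass(frozen=True)
class PairingStateProfile:
    """Per-position probabilities of the three pairing states."""

    p_down: np.ndarray    # paired with a partner closer to the 3' end
    p_up: np.ndarray      # paired with a partner closer to the 5' end
    p_unpaired: np.ndarray

    def __post_init__(self) -> None:
        for comp in (self.p_down, self.p_up, self.p_unpaired):
            if (comp < -_TOL).any() or (comp > 1 + _TOL).any():
                raise ValueError("profile components must lie in [0, 1]")
        total = self.p_down + self.p_up + self.p_unpaired
        if not np.allclose(total, 1.0, atol=_TOL):
            raise ValueError("profile components must sum to 1 at every position")


@dataclass(frozen=True)
class MatchScoreParams:
    """Weights of the structural match score.

    `alpha1` rewards agreement of paired state (both downstream or both
    upstream), `alpha2` agreement of the unpaired state, and `alpha3` is the
    constant floor that sets the score of a paired-vs-unpaired mismatch.
    Defaults (1.0, 0.8, 0.5); setting (1, 1, 0) recovers the classic
    pair-probability-only comparison score.
    """

    alpha1: float = 1.0
    alpha2: float = 0.8
    alpha3: float = 0.5

    def __post_init__(self) -> None:
        if min(self.alpha1, self.alpha2, self.alpha3) < 0:
            raise ValueError("match-score weights must be nonnegative")


def pairing_state_profile(p: PairProbabilityMatrix) -> PairingStateProfile:
    """Row/column sums of the pair-probability matrix -> state profile."""
    down = p.p.sum(axis=1)
    up = p.p.sum(axis=0)
    unpaired = 1.0 - down - up
    return PairingStateProfile(down, up, np.clip(unpaired, 0.0, 1.0))


def match_score_matrix(a: PairingStateProfile, b: PairingStateProfile,
                       params: MatchScoreParams) -> np.ndarray:
    """Elementwise structural match score between all position pairs.

    rho(i, k) = a1*(sqrt(Pdown_i*Pdown_k) + sqrt(Pup_i*Pup_k))
              + a2*sqrt(Punp_i*Punp_k) + a3, bounded between a3 and
    max(a1, a2) + a3.
    """
    rho = (params.alpha1 * (np.sqrt(np.outer(a.p_down, b.p_down))
                            + np.sqrt(np.outer(a.p_up, b.p_up)))
           + params.alpha2 * np.sqrt(np.outer(a.p_unpaired, b.p_unpaired))
           + params.alpha3)
    return rho


def proclivity(p_n: PairProbabilityMatrix, post_mn: CoincidencePosteriors,
               cutoff: float = DEFAULT_COINCIDENCE_CUTOFF) -> np.ndarray:
    """Pairing proclivity for the target sequence inferred from one homolog.

    proclivity(i, j) = sum_{k < l} P_n(k, l) * C(i, k) * C(j, l), where C is
    the co-incidence posterior of (target, homolog) and the sums are
    restricted to candidate columns whose co-incidence probability is at
    least `cutoff` (entries below the cutoff are outside the candidate
    sets).  Returns a strictly upper-triangular nonnegative matrix.
    """
    if not (0 <= cutoff < 1):
        raise ValueError("cutoff must lie in [0, 1)")
    c = post_mn.coincidence
    cs = np.where(c >= cutoff, c, 0.0)
    out = cs @ p_n.p @ cs.T
    return np.triu(out, k=1)


def extrinsic_information(
        target: int,
        proclivities: Mapping[int, np.ndarray],
        identities: Mapping[int, float],
        n_target: int | None = None) -> np.ndarray:
    """Identity-weighted, max-normalized sum of proclivities from homologs.

    Each homolog n contributes (1 - psi_{target,n}) * proclivity(n->target);
    the sum is scaled so its maximum entry is exactly one.  An identically
    zero sum (identical sequences, or no homologs) yields the zero matrix,
    which is neutral under the (1 + kappa * extrinsic) pair multiplier.
    """
    if set(proclivities) != set(identities):
        raise ValueError("proclivity and identity keys must agree")
    if target in proclivities:
        raise ValueError("target sequence cannot contribute to its own extrinsic")
    total: np.ndarray | None = None
    for n, mat in sorted(proclivities.items()):
        contrib = (1.0 - identities[n]) * mat
        total = contrib if total is None else total + contrib
    if total is None:
        if n_target is None:
            raise ValueError("no homologs given and no target dimension to "
                             "shape the zero matrix")
        return np.zeros((n_target, n_target))
    peak = total.max()
    if peak <= 0.0:
        return np.zeros_like(total)
    return total / peak
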