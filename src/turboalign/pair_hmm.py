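"""Pairwise alignment hidden Markov model.

A three-state pair HMM (ALN, INS1, INS2) aligns two RNA sequences.  The
forward-backward algorithm yields, for every position pair (i, k), the
posterior probability that the two nucleotides are *co-incident* (aligned, or
one lies in an insert run immediately following an aligned nucleotide) and
the posterior probability that they are strictly *aligned* (the HMM is in the
ALN state).  A structural match score can be supplied as a multiplicative
prior on the ALN terms of the recursions, which is how predicted base-pairing
information feeds back into the alignment.

All dynamic programming runs in log space (numba kernels), so sequences up to
a thousand nucleotides pose no over/underflow risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .io_formats import RnaSequence

ALN, INS1, INS2 = 0, 1, 2
_TOL = 1e-12


@dataclass(frozen=True)
class HmmParameters:
    """Transition and emission tables of the three-state alignment HMM.

    `transition[s, t]` is P(next state t | current state s); the chain is
    entered in ALN at the (0, 0) boundary cell, and no explicit end state is
    modelled (the total path weight is read off the (N_m, N_n) corner).
    `emission_pair[y, z]` is the joint nucleotide emission in ALN and
    `emission_single[y]` the single-nucleotide emission shared by INS1/INS2,
    both indexed over A,C,G,U.
    """

    transition: np.ndarray
    emission_pair: np.ndarray
    emission_single: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.transition, dtype=float)
        ep = np.asarray(self.emission_pair, dtype=float)
        es = np.asarray(self.emission_single, dtype=float)
        if t.shape != (3, 3) or ep.shape != (4, 4) or es.shape != (4,):
            raise ValueError("parameter table shapes must be (3,3), (4,4), (4,)")
        if (t < 0).any() or (ep < 0).any() or (es < 0).any():
            raise ValueError("probabilities must be nonnegative")
        if not np.allclose(t.sum(axis=1), 1.0, atol=_TOL):
            raise ValueError("transition rows must sum to 1")
        if abs(ep.sum() - 1.0) > _TOL or abs(es.sum() - 1.0) > _TOL:
            raise ValueError("emission tables must sum to 1")
        object.__setattr__(self, "transition", t)
        object.__setattr__(self, "emission_pair", ep)
        object.__setattr__(self, "emission_single", es)


def default_hmm_parameters() -> HmmParameters:
    """Documented default parameter set.

    ALN is strongly self-transitioning (0.95) with symmetric gap opening;
    insert states extend with probability 0.3 and return to ALN otherwise
    (a small INS1<->INS2 leak keeps the chain ergodic).  The match emission
    favors identical nucleotides 5:1 over each mismatch; insert emissions are
    uniform.
    """
    transition = np.array([
        [0.95, 0.025, 0.025],
        [0.69, 0.30, 0.01],
        [0.69, 0.01, 0.30],
    ])
    emission_pair = np.full((4, 4), 1.0 / 32.0)
    np.fill_diagonal(emission_pair, 5.0 / 32.0)
    emission_single = np.full(4, 0.25)
    return HmmParameters(transition, emission_pair, emission_single)


@dataclass(frozen=True)
class CoincidencePosteriors:
    """Posterior matrices for one ordered sequence pair plus their identity.

    `coincidence[i, k]` sums the ALN/INS1/INS2 state posteriors at cell
    (i, k); `aligned[i, k]` keeps the ALN state only.  `identity` is the
    fraction of identical aligned columns in the posterior-decoded pairwise
    alignment (gap columns included in the denominator).
    """

    coincidence: np.ndarray
    aligned: np.ndarray
    identity: float

    def transposed(self) -> "CoincidencePosteriors":
        return CoincidencePosteriors(
            np.ascontiguousarray(self.coincidence.T),
            np.ascontiguousarray(self.aligned.T),
            self.identity,
        )


@njit(cache=True)
def _lse3(a, b, c):
    m = a
    if b > m:
        m = b
    if c > m:
        m = c
    if m == -np.inf:
        return -np.inf
    return m + np.log(np.exp(a - m) + np.exp(b - m) + np.exp(c - m))


@njit(cache=True)
def _forward(xs, ys, lt, lep, les, lrho):
    n1, n2 = xs.shape[0], ys.shape[0]
    fa = np.full((3, n1 + 1, n2 + 1), -np.inf)
    fa[ALN, 0, 0] = 0.0
    for i in range(n1 + 1):
        for k in range(n2 + 1):
            if i == 0 and k == 0:
                continue
            if i > 0 and k > 0:
                e = lep[xs[i - 1], ys[k - 1]] + lrho[i - 1, k - 1]
                fa[ALN, i, k] = e + _lse3(
                    lt[ALN, ALN] + fa[ALN, i - 1, k - 1],
                    lt[INS1, ALN] + fa[INS1, i - 1, k - 1],
                    lt[INS2, ALN] + fa[INS2, i - 1, k - 1],
                )
            if i > 0:
                e = les[xs[i - 1]]
                fa[INS1, i, k] = e + _lse3(
                    lt[ALN, INS1] + fa[ALN, i - 1, k],
                    lt[INS1, INS1] + fa[INS1, i - 1, k],
                    lt[INS2, INS1] + fa[INS2, i - 1, k],
                )
            if k > 0:
                e = les[ys[k - 1]]
                fa[INS2, i, k] = e + _lse3(
                    lt[ALN, INS2] + fa[ALN, i, k - 1],
                    lt[INS1, INS2] + fa[INS1, i, k - 1],
                    lt[INS2, INS2] + fa[INS2, i, k - 1],
                )
    return fa


@njit(cache=True)
def _backward(xs, ys, lt, lep, les, lrho):
    n1, n2 = xs.shape[0], ys.shape[0]
    bb = np.full((3, n1 + 1, n2 + 1), -np.inf)
    for s in range(3):
        bb[s, n1, n2] = 0.0
    for i in range(n1, -1, -1):
        for k in range(n2, -1, -1):
            if i == n1 and k == n2:
                continue
            t_aln = -np.inf
            if i < n1 and k < n2:
                t_aln = lep[xs[i], ys[k]] + lrho[i, k] + bb[ALN, i + 1, k + 1]
            t_i1 = -np.inf
            if i < n1:
                t_i1 = les[xs[i]] + bb[INS1, i + 1, k]
            t_i2 = -np.inf
            if k < n2:
                t_i2 = les[ys[k]] + bb[INS2, i, k + 1]
            for s in range(3):
                bb[s, i, k] = _lse3(
                    lt[s, ALN] + t_aln,
                    lt[s, INS1] + t_i1,
                    lt[s, INS2] + t_i2,
                )
    return bb


@njit(cache=True)
def _decode_dp(mat):
    n1, n2 = mat.shape
    dp = np.zeros((n1 + 1, n2 + 1))
    for i in range(1, n1 + 1):
        for k in range(1, n2 + 1):
            best = dp[i - 1, k - 1] + mat[i - 1, k - 1]
            if dp[i - 1, k] > best:
                best = dp[i - 1, k]
            if dp[i, k - 1] > best:
                best = dp[i, k - 1]
            dp[i, k] = best
    return dp


def mea_decode(mat: np.ndarray) -> tuple[list[tuple[int, int]], float]:
    """Monotone alignment maximizing the summed cell values of `mat`.

    Returns the matched cells (0-based) and the optimal score.  Ties are
    broken deterministically: match first, then advance in the first
    sequence.
    """
    dp = _decode_dp(np.ascontiguousarray(mat, dtype=float))
    n1, n2 = mat.shape
    i, k = n1, n2
    matches: list[tuple[int, int]] = []
    while i > 0 and k > 0:
        if dp[i, k] == dp[i - 1, k - 1] + mat[i - 1, k - 1]:
            matches.append((i - 1, k - 1))
            i -= 1
            k -= 1
        elif dp[i, k] == dp[i - 1, k]:
            i -= 1
        else:
            k -= 1
    matches.reverse()
    return matches, float(dp[n1, n2])


def pairwise_identity(post: CoincidencePosteriors, x: RnaSequence,
                      y: RnaSequence) -> float:
    """Fraction of identical aligned columns in the decoded pairwise alignment.

    The decoded alignment maximizes the summed aligned-state posteriors; its
    length (matches plus gap columns, terminal gaps included) is the
    denominator.
    """
    matches, _ = mea_decode(post.aligned)
    same = sum(1 for i, k in matches if x.residues[i] == y.residues[k])
    length = x.length + y.length - len(matches)
    return same / length if length else 1.0


def compute_posteriors(x: RnaSequence, y: RnaSequence,
                       params: HmmParameters,
                       rho: np.ndarray | None = None) -> CoincidencePosteriors:
    """Forward-backward posteriors for the pair (x, y).

    `rho`, if given, is an N_x x N_y matrix of strictly positive match-score
    priors multiplied into the ALN terms of the recursions; its global scale
    cancels in the posterior ratio.  Absent `rho` is equivalent to an
    all-ones prior (the initial, sequence-only pass).
    """
    n1, n2 = x.length, y.length
    if rho is None:
        lrho = np.zeros((n1, n2))
    else:
        rho = np.asarray(rho, dtype=float)
        if rho.shape != (n1, n2):
            raise ValueError(f"rho shape {rho.shape} != ({n1}, {n2})")
        if (rho <= 0).any():
            raise ValueError("match-score prior entries must be strictly positive")
        lrho = np.log(rho)
    with np.errstate(divide="ignore"):
        lt = np.log(params.transition)
        lep = np.log(params.emission_pair)
        les = np.log(params.emission_single)
    xs, ys = x.encoded(), y.encoded()
    fa = _forward(xs, ys, lt, lep, les, lrho)
    bb = _backward(xs, ys, lt, lep, les, lrho)
    logz = _lse3(fa[ALN, n1, n2], fa[INS1, n1, n2], fa[INS2, n1, n2])
    if logz == -np.inf or not np.isfinite(logz):
        raise ValueError("zero total path weight: degenerate HMM parameters")
    post = np.exp(fa[:, 1:, 1:] + bb[:, 1:, 1:] - logz)
    coincidence = np.clip(post.sum(axis=0), 0.0, 1.0)
    aligned = np.clip(post[ALN], 0.0, 1.0)
    out = CoincidencePosteriors(coincidence, aligned, 0.0)
    psi = pairwise_identity(out, x, y)
    return CoincidencePosteriors(coincidence, aligned, psi)
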