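"""Orchestration of the iterative folding-and-alignment loop.

Initialization computes sequence-only pairwise alignment posteriors (no
structural prior) and plain partition-function base-pair probabilities.
Each iteration then (3) builds match scores from the current pair
probabilities, (4) re-estimates the alignment posteriors with the match
score as prior, (5) combines pair probabilities and the fresh posteriors
into per-sequence extrinsic matrices, and (6) re-folds every sequence with
the extrinsic bonus.  After a fixed number of iterations (no convergence
test), the final posteriors feed the progressive multiple alignment and the
final pair probabilities feed per-sequence structure prediction.

Pairwise identities are computed once at initialization from the
sequence-only alignments and held fixed, keeping the extrinsic weights
stable across iterations.  The whole pipeline is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import coupling, mea, msa
from .io_formats import MultipleAlignment, SecondaryStructure, SequenceSet
from .pair_hmm import (CoincidencePosteriors, HmmParameters,
                       compute_posteriors, default_hmm_parameters)
from .partition import (DEFAULT_KAPPA, EnergyModel, PairProbabilityMatrix,
                        pair_probabilities)

MIN_SEQUENCE_LENGTH = 4


@dataclass(frozen=True)
class TurboConfig:
    """Tunable parameters of the whole pipeline, with shipped defaults."""

    iterations: int = 3
    match_params: coupling.MatchScoreParams = field(
        default_factory=coupling.MatchScoreParams)
    kappa: float = DEFAULT_KAPPA
    coincidence_cutoff: float = coupling.DEFAULT_COINCIDENCE_CUTOFF
    mode: str = "mea"
    threshold: float = mea.DEFAULT_THRESHOLD
    energy_model: EnergyModel = field(default_factory=EnergyModel)
    hmm_params: HmmParameters = field(default_factory=default_hmm_parameters)

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if not (0 < self.threshold <= 1):
            raise ValueError("threshold must lie in (0, 1]")
        if self.mode not in ("mea", "threshold"):
            raise ValueError("mode must be 'mea' or 'threshold'")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


@dataclass(frozen=True)
class TurboState:
    """Everything the loop cycles: per-sequence pair probabilities,
    per-pair alignment posteriors, fixed identities, iteration count."""

    seqs: SequenceSet
    pair_probs: tuple[PairProbabilityMatrix, ...]
    posteriors: dict[tuple[int, int], CoincidencePosteriors]
    identities: dict[tuple[int, int], float]
    iteration: int = 0

    def identity(self, m: int, n: int) -> float:
        return self.identities[(m, n) if m < n else (n, m)]

    def posterior(self, m: int, n: int) -> CoincidencePosteriors:
        """Posteriors oriented as (m rows, n columns)."""
        if (m, n) in self.posteriors:
            return self.posteriors[(m, n)]
        return self.posteriors[(n, m)].transposed()


def initialize(seqs: SequenceSet, cfg: TurboConfig) -> TurboState:
    """Sequence-only HMM pass and plain partition pass (steps 1-2)."""
    for s in seqs:
        if s.length < MIN_SEQUENCE_LENGTH:
            raise ValueError(
                f"sequence {s.id!r} is shorter than {MIN_SEQUENCE_LENGTH} nt; "
                "folding is degenerate below the minimum hairpin span")
    posteriors = {}
    identities = {}
    for m in range(seqs.H):
        for n in range(m + 1, seqs.H):
            post = compute_posteriors(seqs[m], seqs[n], cfg.hmm_params)
            posteriors[(m, n)] = post
            identities[(m, n)] = post.identity
    pair_probs = tuple(pair_probabilities(s, cfg.energy_model) for s in seqs)
    return TurboState(seqs, pair_probs, posteriors, identities, iteration=0)


def iterate_once(state: TurboState, cfg: TurboConfig) -> TurboState:
    """One pass of the loop (steps 3-6)."""
    seqs = state.seqs
    H = seqs.H
    profiles = [coupling.pairing_state_profile(p) for p in state.pair_probs]
    # (3) match scores, (4) posterior re-estimation with the prior
    posteriors = {}
    for m in range(H):
        for n in range(m + 1, H):
            rho = coupling.match_score_matrix(profiles[m], profiles[n],
                                              cfg.match_params)
            post = compute_posteriors(seqs[m], seqs[n], cfg.hmm_params, rho=rho)
            posteriors[(m, n)] = post
    interim = replace(state, posteriors=posteriors)
    # (5) extrinsic from previous pair probabilities + new posteriors
    extrinsics = []
    for m in range(H):
        procs = {}
        psis = {}
        for n in range(H):
            if n == m:
                continue
            procs[n] = coupling.proclivity(state.pair_probs[n],
                                           interim.posterior(m, n),
                                           cfg.coincidence_cutoff)
            psis[n] = state.identity(m, n)
        extrinsics.append(coupling.extrinsic_information(
            m, procs, psis, n_target=seqs[m].length))
    # (6) re-fold with the extrinsic bonus
    pair_probs = tuple(
        pair_probabilities(seqs[m], cfg.energy_model,
                           extrinsic=extrinsics[m], kappa=cfg.kappa)
        for m in range(H))
    return TurboState(seqs, pair_probs, posteriors, state.identities,
                      iteration=state.iteration + 1)


def predict_structures(state: TurboState,
                       cfg: TurboConfig) -> list[SecondaryStructure]:
    """Step 8: per-sequence structure from the final pair probabilities."""
    if cfg.mode == "mea":
        return [mea.mea_structure(p) for p in state.pair_probs]
    return [mea.threshold_structure(p, cfg.threshold) for p in state.pair_probs]


def run(seqs: SequenceSet, cfg: TurboConfig | None = None
        ) -> tuple[TurboState, MultipleAlignment | None,
                   list[SecondaryStructure]]:
    """Full pipeline: initialize, iterate, align (step 7), predict (step 8).

    A single-sequence input skips the alignment and reduces to plain
    single-sequence folding plus structure prediction.
    """
    if cfg is None:
        cfg = TurboConfig()
    state = initialize(seqs, cfg)
    for _ in range(cfg.iterations):
        state = iterate_once(state, cfg)
    alignment = msa.compute_msa(state, seqs) if seqs.H > 1 else None
    structures = predict_structures(state, cfg)
    return state, alignment, structures


def states_equal(a: TurboState, b: TurboState, atol: float = 0.0) -> bool:
    """Exact (or toleranced) equality of the cycled quantities; used by the
    determinism and neutral-coupling checks."""
    if a.seqs != b.seqs or set(a.posteriors) != set(b.posteriors):
        return False
    for pa, pb in zip(a.pair_probs, b.pair_probs):
        if not np.allclose(pa.p, pb.p, atol=atol, rtol=0.0):
            return False
    for key in a.posteriors:
        qa, qb = a.posteriors[key], b.posteriors[key]
        if not (np.allclose(qa.coincidence, qb.coincidence, atol=atol, rtol=0.0)
                and np.allclose(qa.aligned, qb.aligned, atol=atol, rtol=0.0)):
            return False
    return True
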