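# Methods

This note documents the models, the shipped parameters, the synthetic-data
generator, and the numerical and design choices behind `turboalign`.

## Pipeline

The pipeline has eight stages.  (1) For every sequence pair, a pair HMM is
run forward–backward to obtain posterior co-incidence and aligned-state
probabilities; pairwise identities are recorded here and held fixed.
(2) Each sequence is folded with the plain partition function.  Then a
loop, iterated a fixed number of times (default 3, no convergence test):
(3) match scores are built from the current pair probabilities for every
sequence pair; (4) the HMM posteriors are re-estimated with the match
score as a prior; (5) extrinsic matrices are assembled for every sequence
from the *previous* pair probabilities and the *just-updated* posteriors;
(6) every sequence is re-folded with its extrinsic bonus.  After the loop,
(7) the aligned posteriors are consistency-transformed once and a
progressive alignment is computed, and (8) a structure is predicted per
sequence.  Every stage is deterministic; two runs on the same input are
bitwise identical.

Holding the identities psi fixed at their sequence-only values keeps the
extrinsic weights `(1 − psi)` stable across iterations; re-estimating them
from structurally sharpened alignments would let the weighting drift with
the very quantity it regularizes.

## Pair HMM

Three states — ALN (joint emission of one nucleotide per sequence), INS1
and INS2 (single emission plus an implicit gap) — with a 3×3 transition
matrix.  The chain starts in ALN at the (0,0) boundary; no end state is
modelled, and the total path weight is read off the terminal corner, which
is also the normalizer of both posterior ratios.

The exact numeric parameters of the alignment HMMs used by comparable
tools are trained on curated alignments and are not reproduced here; the
shipped defaults are documented stand-ins, overridable through the config
file:

| parameter | default | rationale |
|---|---|---|
| ALN self-transition | 0.95 | alignments are mostly matches at tool scale |
| gap open (ALN→INS) | 0.025 each | symmetric |
| gap extend (INS→INS) | 0.30 | mean gap length 1/(1−0.3) ≈ 1.4 nt |
| INS1↔INS2 leak | 0.01 | keeps the chain ergodic |
| match emission | identical 5:1 over each mismatch | moderate identity signal |
| insert emission | uniform 0.25 | uninformative |

The match-score prior `rho` multiplies the ALN terms of both recursions
directly, with no explicit normalization: the posterior ratio absorbs any
global scale, and a constant `rho = 1` reproduces the prior-free posteriors
to machine precision (this is asserted by tests).  Arbitrary constant
priors reweight paths by their number of match states and are therefore
*not* neutral — only the unit constant is.

Pairwise identity psi is computed by posterior decoding: a monotone-path
dynamic program maximizes the summed aligned-state posteriors, and psi is
the fraction of decoded columns (gap columns, terminal gaps included) whose
two residues are present and identical.

All HMM dynamic programming runs in log space, so sequences of at least a
thousand nucleotides pose no underflow risk (asserted at N = 1000).

## Folding model and partition function

The partition function sums multiplicative weights over all non-crossing
structures built from canonical pairs (AU, GC, GU and reversals).  Weights
factor over the loop decomposition: per-pair factors, a stacking bonus
`stack_scale · sqrt(w_pq · w_rs)` for helically adjacent pairs,
exponentially decaying hairpin/internal/bulge factors in the unpaired
length, and a linear multibranch cost (closing factor × per-branch factor
× per-unpaired-nucleotide factor).  Shipped defaults: pair weights
GC/CG 2.2, AU/UA 1.4, GU/UG 1.15; stack scale 1.8; hairpin 0.003·e^(−0.05·(L−3));
internal 0.02·e^(−0.2·(s−2)); bulge 0.05·e^(−0.3·(s−1)); multibranch
(0.01, 0.4, 0.9); minimum hairpin 3 nt.  The numbers were chosen once so
that designed stems of 4–6 bp dominate the open chain and a multibranch
cloverleaf can close — i.e. so the intrinsic term carries real folding
information — and they are deliberately *not* a fit to measured
thermodynamics.  The model is pluggable; anything implementing the same
factor tables can replace it.

Inside–outside recursions are O(N³): the internal-loop scan is capped at a
total unpaired span of 30 (structures with larger internal loops have
weight zero, in the dynamic program and in the enumeration oracle alike),
and the outside multibranch term is reduced to O(N³) with two aggregate
arrays accumulated span-by-span.  Recursions run in plain weight space
(not log space): with the shipped factors the partition function stays
comfortably within double range at tool scale (~10²–10³ nt); extremely
long, perfectly complementary inputs could overflow, a known limitation.

Extrinsic information enters as a per-pair multiplier `(1 + kappa·P~(i,j))`
on the pair's equilibrium factor, default `kappa = 10`.  The precise
pseudo-free-energy form used by prior work on this coupling is not
reproduced here; this form was chosen because it is neutral at `P~ = 0`
(which makes the all-identical-sequences case, where the `(1 − psi)`
weights vanish, exactly equivalent to plain folding), bounded, and
monotone in the evidence.

Correctness of the whole folding stack is established against an
exhaustive enumeration oracle (all non-crossing canonical structures,
N ≤ 16, identical weight semantics) at 1e-9 across random toy models, with
and without extrinsic bonuses.  Enumeration-oracle toy models use minimum
hairpin sizes of 1–3 so that multibranch loops occur within N ≤ 12.

## Coupling

Match score: `rho(i,k) = a1(sqrt(P_< P_<) + sqrt(P_> P_>)) + a2 sqrt(P_o P_o) + a3`
with defaults (1.0, 0.8, 0.5).  `rho` is bounded between `a3` and
`max(a1, a2) + a3` (property-tested).  Proclivity sums are restricted to
candidate columns whose co-incidence probability is at least 0.01
(inclusive — entries *below* the cutoff are outside the candidate sets);
the cutoff is a speed approximation whose effect is bounded, not a change
of semantics.  The extrinsic sum is max-normalized; an identically zero
sum (identical sequences, or a single input sequence) yields the zero
matrix, which the `(1 + kappa·P~)` multiplier makes exactly neutral —
this avoids the division by zero that max-normalization would otherwise
hit.

Co-incidence posteriors (all three states) are used for the proclivity;
aligned-state posteriors (ALN only) are used for the consistency
transform.  Both matrices are therefore retained per pair.

## Multiple alignment

The consistency transformation averages `A_mo·A_on` over every sequence
`o` of the set, each endpoint included with an identity self-posterior, so
for two sequences the transform is exactly the identity.  It is applied
once.  Third-sequence intermediaries are sparsified at 1e-3 before the
products (the endpoint identity terms are kept exact); the floor is
configurable.

The guide tree is greedy agglomeration on `E(m, n) =` (maximum summed
transformed posterior over a monotone alignment) `/ min(N_m, N_n)`, with
size-weighted average linkage (which keeps merge scores non-increasing)
and deterministic smallest-index tie-breaking.  Profile merges maximize
the sum over cross-group sequence pairs of `P'(i, k)` for co-columned
residues; gaps score zero everywhere (terminal and internal alike, no
affine profile — discrimination comes from the posteriors), and existing
columns are never split ("once a gap, always a gap").  No post-progressive
iterative refinement is performed.

## Structure prediction

The MEA objective fixes the weights printed above (2 per pair, 1 per
unpaired position); no tunable accuracy trade-off is exposed.  The
interval dynamic program breaks ties deterministically — fewer pairs
first, then the lexicographically smallest pair list.  Threshold mode
keeps pairs with `P(i, j) > t` (default 0.5, which is conflict-free by the
row-sum bound); conflicts at lower thresholds are resolved greedily by
descending probability.  Crossing pairs can arise only in threshold mode
and are representable in CT output; the dot-bracket writer rejects them.

## Synthetic families

The generator evolves a designed seed (default: a ~116-nt multibranch
fold — an 8-bp closing stem and four 7-bp hairpin arms, stems sampled
GC-enriched) into descendants on a star phylogeny.  Paired positions
mutate as pairs: at the compensatory fraction (default 1.0) the pair is
replaced by a uniformly chosen different canonical pair; otherwise a
single side mutates and the pair is recorded as destroyed if it becomes
non-canonical.  Loop positions substitute freely (rate 0.3, matching a
mean pairwise identity near 0.5 — the regime where structural information
should matter), and indels (rate 0.03 per loop position, length ≤ 3) are
confined to loops so that the truth structures remain well-defined.  The
true alignment keeps independent insertions from different descendants in
separate columns.  An optional structural insert places a 14-nt hairpin
into one descendant's largest loop, emulating the variable structure
elements of families like RNase P.

A closed-form expectation for the pairwise identity under the substitution
model is provided and checked against realized families.  What the
generator does *not* emulate: tree-shaped (non-star) phylogenies beyond
the two-level option, realistic indel length distributions, rate
heterogeneity, non-canonical pairs, and pseudoknots.  Tests passing on
these fixtures show the information flow works when structure genuinely is
conserved and indels are loop-confined; they do not certify accuracy on
real families, whose energy landscape the toy folding model only sketches.

## Evaluation

Alignment scores compare aligned residue pairs (same column, both residues
present) exactly — no slippage.  Structure scores credit a predicted pair
`(i, j)` if `(i, j)`, `(i±1, j)` or `(i, j±1)` is in the reference, each
reference pair creditable once (predicted pairs matched greedily in sorted
order, exact match tried first).  Empty reference or prediction yields a
flagged zero rather than an error.

## Known limitations

- The toy energy model limits structure PPV; since the alignment prior is
  built from predicted pairing states, residual structure error can shift
  gap placement by a column or two in otherwise easy alignments — the
  alignment side inherits the folding side's accuracy ceiling.
- Weight-space partition recursions can overflow on pathological
  (long, perfectly self-complementary) inputs.
- The progressive aligner has no anchoring or banding; inputs are expected
  to be tens of sequences of hundreds of nucleotides, not thousands.
- Ambiguity codes are rejected at input rather than resolved.
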