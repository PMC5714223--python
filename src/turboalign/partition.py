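"""Equilibrium base-pair probabilities from a partition function.

The partition function sums multiplicative equilibrium weights over all
non-crossing canonical secondary structures of one sequence.  The weight of
a structure factors over its loop decomposition: a factor per canonical pair,
a stacking bonus for helically adjacent pairs, and hairpin / internal /
bulge / multibranch loop factors.  Base-pair probabilities are the
structure-weighted marginals, computed with inside-outside dynamic
programming in O(N^3) time (internal loops capped at a total unpaired span
of 30, standard practice).

Extrinsic information -- pairing evidence mapped in from homologous
sequences -- enters as a per-pair pseudo-free-energy bonus: the equilibrium
factor of pair (i, j) is multiplied by (1 + kappa * extrinsic[i, j]).  This
form is neutral where the extrinsic matrix is zero, bounded, and monotone in
the extrinsic evidence.

An explicit structure-enumeration oracle with the identical contract is
provided for small sequences; the dynamic program is validated against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .io_formats import BASE_ORDER, RnaSequence

#: canonical pair set, including GU wobble
CANONICAL = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})

DEFAULT_KAPPA = 10.0


@dataclass(frozen=True)
class EnergyModel:
    """A small, self-contained nearest-neighbor-style equilibrium model.

    Weights are dimensionless Boltzmann-like factors (>= 0): `pair_weights`
    per canonical pair; stacking bonus between adjacent pairs pq over rs of
    `stack_scale * sqrt(w_pq * w_rs)`; exponentially decaying hairpin,
    internal and bulge loop factors indexed by unpaired length; and a linear
    multibranch cost (closing factor, per-branch factor, per-unpaired
    factor).  Not a fit to measured thermodynamics -- a documented toy set
    whose role is to carry intrinsic folding information at tool scale.
    """

    pair_weights: dict[str, float] = field(default_factory=lambda: {
        "GC": 2.2, "CG": 2.2, "AU": 1.4, "UA": 1.4, "GU": 1.15, "UG": 1.15,
    })
    stack_scale: float = 1.8
    hairpin_base: float = 0.003
    hairpin_decay: float = 0.05
    internal_base: float = 0.02
    internal_decay: float = 0.2
    bulge_base: float = 0.05
    bulge_decay: float = 0.3
    mb_closing: float = 0.01
    mb_branch: float = 0.4
    mb_unpaired: float = 0.9
    min_hairpin: int = 3
    max_internal: int = 30

    def __post_init__(self) -> None:
        if self.min_hairpin < 1:
            raise ValueError("min_hairpin must be >= 1")
        if set(self.pair_weights) - CANONICAL:
            raise ValueError("pair weights outside the canonical pair set")
        vals = list(self.pair_weights.values()) + [
            self.stack_scale, self.hairpin_base, self.internal_base,
            self.bulge_base, self.mb_closing, self.mb_branch, self.mb_unpaired,
        ]
        if any(v < 0 for v in vals):
            raise ValueError("all equilibrium factors must be nonnegative")

    # -- tables used by the DP kernels (all 0-based) --------------------

    def pair_weight_matrix(self, seq: RnaSequence) -> np.ndarray:
        """(n, n) matrix of pair factors; zero for non-canonical pairs and
        spans at or below the hairpin minimum."""
        n = seq.length
        w = np.zeros((n, n))
        for i in range(n):
            for j in range(i + self.min_hairpin + 1, n):
                w[i, j] = self.pair_weights.get(
                    seq.residues[i] + seq.residues[j], 0.0)
        return w

    def stack_matrix(self, seq: RnaSequence) -> np.ndarray:
        """stack[i, j] = bonus for pair (i, j) stacked directly on (i+1, j-1)."""
        n = seq.length
        s = np.zeros((n, n))
        for i in range(n - 3):
            for j in range(i + 3, n):
                outer = self.pair_weights.get(seq.residues[i] + seq.residues[j], 0.0)
                inner = self.pair_weights.get(
                    seq.residues[i + 1] + seq.residues[j - 1], 0.0)
                if outer > 0 and inner > 0:
                    s[i, j] = self.stack_scale * np.sqrt(outer * inner)
        return s

    def hairpin_array(self, n: int) -> np.ndarray:
        ls = np.arange(n + 1, dtype=float)
        out = self.hairpin_base * np.exp(
            -self.hairpin_decay * np.maximum(ls - self.min_hairpin, 0.0))
        out[:self.min_hairpin] = 0.0
        return out

    def internal_array(self) -> np.ndarray:
        ls = np.arange(self.max_internal + 1, dtype=float)
        out = self.internal_base * np.exp(-self.internal_decay * (ls - 2.0))
        out[0] = 0.0
        return out

    def bulge_array(self) -> np.ndarray:
        ls = np.arange(self.max_internal + 1, dtype=float)
        out = self.bulge_base * np.exp(-self.bulge_decay * (ls - 1.0))
        out[0] = 0.0
        return out


@dataclass(frozen=True)
class PairProbabilityMatrix:
    """Strictly upper-triangular matrix of base-pair probabilities."""

    n: int
    p: np.ndarray

    _ROW_TOL = 1e-9

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (self.n, self.n):
            raise ValueError("probability matrix shape mismatch")
        if np.tril(p).any():
            raise ValueError("matrix must be strictly upper triangular")
        if (p < 0).any() or (p > 1 + self._ROW_TOL).any():
            raise ValueError("pair probabilities must lie in [0, 1]")
        involvement = p.sum(axis=1) + p.sum(axis=0)
        if (involvement > 1 + self._ROW_TOL).any():
            raise ValueError("total pairing involvement exceeds 1 at some position")
        object.__setattr__(self, "p", p)


def unpaired_probabilities(p: PairProbabilityMatrix) -> np.ndarray:
    """P(i unpaired) = 1 - sum_j P(i, j) - sum_j P(j, i), clipped only within
    the matrix validity tolerance."""
    q = 1.0 - p.p.sum(axis=1) - p.p.sum(axis=0)
    if (q < -PairProbabilityMatrix._ROW_TOL).any():
        raise ValueError("invalid pair-probability matrix: involvement > 1")
    return np.clip(q, 0.0, 1.0)


# ---------------------------------------------------------------------------
# inside-outside kernels

@njit(cache=True)
def _inside(pw, stkm, hp, bl, il, upow, mbc, mbb, minh, maxintl):
    n = pw.shape[0]
    zb = np.zeros((n, n))
    zm1 = np.zeros((n, n))
    zm = np.zeros((n, n))
    for span in range(minh + 1, n):
        for i in range(0, n - span):
            j = i + span
            if pw[i, j] > 0.0:
                acc = hp[span - 1]
                # stack / internal / bulge closings
                for s1 in range(0, maxintl + 1):
                    k = i + 1 + s1
                    if k >= j:
                        break
                    for s2 in range(0, maxintl - s1 + 1):
                        l = j - 1 - s2
                        if l - k <= minh:
                            break
                        z = zb[k, l]
                        if z > 0.0:
                            if s1 == 0 and s2 == 0:
                                acc += stkm[i, j] * z
                            elif s1 == 0 or s2 == 0:
                                acc += bl[s1 + s2] * z
                            else:
                                acc += il[s1 + s2] * z
                # multibranch closing
                mb = 0.0
                for k in range(i + 2, j - 1):
                    a = zm[i + 1, k - 1]
                    b = zm1[k, j - 1]
                    if a > 0.0 and b > 0.0:
                        mb += a * b
                acc += mbc * mb
                zb[i, j] = pw[i, j] * acc
            # one-branch multiloop segment starting at i
            s = 0.0
            for l in range(i + minh + 1, j + 1):
                if zb[i, l] > 0.0:
                    s += zb[i, l] * upow[j - l]
            zm1[i, j] = mbb * s
            # >= 1 branch segment, decomposed on the last branch start
            t = 0.0
            for k in range(i, j + 1):
                z1 = zm1[k, j]
                if z1 > 0.0:
                    lead = upow[k - i]
                    if k > i:
                        lead += zm[i, k - 1]
                    t += lead * z1
            zm[i, j] = t
    return zb, zm1, zm


@njit(cache=True)
def _exterior(zb):
    n = zb.shape[0]
    ze5 = np.ones(n + 1)
    for j in range(1, n + 1):
        acc = ze5[j - 1]
        for k in range(1, j + 1):
            z = zb[k - 1, j - 1]
            if z > 0.0:
                acc += ze5[k - 1] * z
        ze5[j] = acc
    ze3 = np.ones(n + 2)
    for i in range(n, 0, -1):
        acc = ze3[i + 1]
        for l in range(i, n + 1):
            z = zb[i - 1, l - 1]
            if z > 0.0:
                acc += z * ze3[l + 1]
        ze3[i] = acc
    return ze5, ze3


@njit(cache=True)
def _outside(pw, stkm, bl, il, upow, mbc, mbb, minh, maxintl,
             zb, zm, ze5, ze3):
    n = pw.shape[0]
    pout = np.zeros((n, n))
    # C[k, j] = sum_{l > j} pw[k,l]*mbc*Pout[k,l] * Zm(j+1, l-1)
    # D[k, j] = sum_{l > j} pw[k,l]*mbc*Pout[k,l] * u^(l-j-1)
    cagg = np.zeros((n, n))
    dagg = np.zeros((n, n))
    for span in range(n - 1, minh, -1):
        for i in range(0, n - span):
            j = i + span
            if pw[i, j] <= 0.0:
                continue
            acc = ze5[i] * ze3[j + 2]
            # enclosing stack / internal / bulge
            for s1 in range(0, maxintl + 1):
                k = i - 1 - s1
                if k < 0:
                    break
                for s2 in range(0, maxintl - s1 + 1):
                    l = j + 1 + s2
                    if l >= n:
                        break
                    if pw[k, l] > 0.0 and pout[k, l] > 0.0:
                        if s1 == 0 and s2 == 0:
                            f = stkm[k, l]
                        elif s1 == 0 or s2 == 0:
                            f = bl[s1 + s2]
                        else:
                            f = il[s1 + s2]
                        acc += f * pw[k, l] * pout[k, l]
            # enclosing multibranch: (i, j) is one branch of a larger loop
            mb = 0.0
            for k in range(0, i):
                c = cagg[k, j]
                d = dagg[k, j]
                if c > 0.0 or d > 0.0:
                    mb += upow[i - k - 1] * c
                    if k + 1 <= i - 1:
                        zl = zm[k + 1, i - 1]
                        if zl > 0.0:
                            mb += zl * (d + c)
            acc += mbb * mb
            pout[i, j] = acc
        # fold this span's cells into the multibranch aggregates
        for i in range(0, n - span):
            j = i + span
            v = pw[i, j] * mbc * pout[i, j]
            if v > 0.0:
                for jj in range(i + 1, j):
                    if jj + 1 <= j - 1:
                        zr = zm[jj + 1, j - 1]
                        if zr > 0.0:
                            cagg[i, jj] += v * zr
                    dagg[i, jj] += v * upow[j - jj - 1]
    return pout


def _effective_pair_weights(seq: RnaSequence, model: EnergyModel,
                            extrinsic: np.ndarray | None,
                            kappa: float) -> np.ndarray:
    pw = model.pair_weight_matrix(seq)
    if extrinsic is not None and kappa != 0.0:
        ex = np.asarray(extrinsic, dtype=float)
        if ex.shape != pw.shape:
            raise ValueError("extrinsic matrix dimensions do not match sequence")
        pw = pw * (1.0 + kappa * ex)
    return pw


def pair_probabilities(seq: RnaSequence, model: EnergyModel,
                       extrinsic: np.ndarray | None = None,
                       kappa: float = 0.0) -> PairProbabilityMatrix:
    """Base-pair probabilities P(i, j) under the equilibrium model.

    With `extrinsic` present and `kappa > 0`, each pair's factor is
    multiplied by (1 + kappa * extrinsic[i, j]); kappa = 0 or an absent
    matrix reduces to the plain partition function.
    """
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    n = seq.length
    pw = _effective_pair_weights(seq, model, extrinsic, kappa)
    stkm = model.stack_matrix(seq)
    hp = model.hairpin_array(n)
    bl = model.bulge_array()
    il = model.internal_array()
    upow = model.mb_unpaired ** np.arange(n + 1, dtype=float)
    zb, _, zm = _inside(pw, stkm, hp, bl, il, upow,
                        model.mb_closing, model.mb_branch,
                        model.min_hairpin, model.max_internal)
    ze5, ze3 = _exterior(zb)
    z = ze5[n]
    if not np.isfinite(z) or z < 1.0:
        # the open (pair-free) structure always contributes weight 1
        raise RuntimeError("partition function lost the open-structure term")
    pout = _outside(pw, stkm, bl, il, upow, model.mb_closing, model.mb_branch,
                    model.min_hairpin, model.max_internal, zb, zm, ze5, ze3)
    p = zb * pout / z
    p = np.triu(np.clip(p, 0.0, 1.0), k=1)
    return PairProbabilityMatrix(n, p)


# ---------------------------------------------------------------------------
# enumeration oracle

_ORACLE_MAX_N = 16


def _enumerate_pairsets(pairable: np.ndarray, minh: int) -> list[tuple[tuple[int, int], ...]]:
    n = pairable.shape[0]
    memo: dict[tuple[int, int], list[tuple[tuple[int, int], ...]]] = {}

    def rec(i: int, j: int) -> list[tuple[tuple[int, int], ...]]:
        if j - i <= minh:
            return [()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = list(rec(i + 1, j))
        for k in range(i + minh + 1, j + 1):
            if pairable[i, k]:
                for inner in rec(i + 1, k - 1):
                    for rest in rec(k + 1, j):
                        out.append(((i, k),) + inner + rest)
        memo[key] = out
        return out

    return rec(0, n - 1)


def _structure_weight(pairs: tuple[tuple[int, int], ...], pw, stkm, hp, bl, il,
                      model: EnergyModel) -> float:
    w = 1.0
    sorted_pairs = sorted(pairs)
    partner = {}
    for i, j in sorted_pairs:
        partner[i] = j
        w *= pw[i, j]
    for i, j in sorted_pairs:
        # walk the loop closed by (i, j): direct children and unpaired count
        children = []
        unpaired = 0
        k = i + 1
        while k < j:
            if k in partner and partner[k] > k:
                children.append((k, partner[k]))
                k = partner[k] + 1
            else:
                unpaired += 1
                k += 1
        if not children:
            w *= hp[j - i - 1]
        elif len(children) == 1:
            (ci, cj) = children[0]
            s1, s2 = ci - i - 1, j - cj - 1
            if s1 + s2 == 0:
                w *= stkm[i, j]
            elif s1 + s2 > model.max_internal:
                return 0.0
            elif s1 == 0 or s2 == 0:
                w *= bl[s1 + s2]
            else:
                w *= il[s1 + s2]
        else:
            w *= (model.mb_closing * model.mb_branch ** len(children)
                  * model.mb_unpaired ** unpaired)
    return w


def enumerate_structures_oracle(seq: RnaSequence, model: EnergyModel,
                                extrinsic: np.ndarray | None = None,
                                kappa: float = 0.0) -> PairProbabilityMatrix:
    """Brute-force marginals by enumerating every non-crossing canonical
    structure (N <= 16).  Same contract as `pair_probabilities`."""
    n = seq.length
    if n > _ORACLE_MAX_N:
        raise ValueError(f"oracle limited to N <= {_ORACLE_MAX_N}")
    pw = _effective_pair_weights(seq, model, extrinsic, kappa)
    stkm = model.stack_matrix(seq)
    hp = model.hairpin_array(n)
    bl = model.bulge_array()
    il = model.internal_array()
    total = 0.0
    mass = np.zeros((n, n))
    for pairs in _enumerate_pairsets(pw > 0, model.min_hairpin):
        w = _structure_weight(pairs, pw, stkm, hp, bl, il, model)
        total += w
        for i, j in pairs:
            mass[i, j] += w
    p = np.triu(np.clip(mass / total, 0.0, 1.0), k=1)
    return PairProbabilityMatrix(n, p)
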