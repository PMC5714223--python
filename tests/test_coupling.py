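import numpy as np
import pytest
from helpers import random_pair_matrix, random_rna
from hypothesis import given, settings
from hypothesis import strategies as st

from turboalign.coupling import (MatchScoreParams, extrinsic_information,
                                 match_score_matrix, pairing_state_profile,
                                 proclivity)
from turboalign.pair_hmm import CoincidencePosteriors
from turboalign.partition import EnergyModel, PairProbabilityMatrix, \
    enumerate_structures_oracle


def _posteriors(co):
    return CoincidencePosteriors(co, co * 0.5, 0.5)


class TestPairingStateProfile:
    def test_zero_matrix_fully_unpaired(self):
        prof = pairing_state_profile(PairProbabilityMatrix(4, np.zeros((4, 4))))
        assert np.array_equal(prof.p_unpaired, np.ones(4))

    def test_certain_pair_down_and_up(self):
        p = np.zeros((5, 5))
        p[0, 4] = 1.0
        prof = pairing_state_profile(PairProbabilityMatrix(5, p))
        assert prof.p_down[0] == 1.0 and prof.p_up[4] == 1.0
        assert prof.p_unpaired[0] == prof.p_unpaired[4] == 0.0

    def test_from_partition_oracle(self, rng):
        seq = random_rna(rng, 10)
        ppm = enumerate_structures_oracle(seq, EnergyModel(min_hairpin=2))
        prof = pairing_state_profile(ppm)
        assert np.allclose(prof.p_down, ppm.p.sum(axis=1))
        assert np.allclose(prof.p_up, ppm.p.sum(axis=0))
        assert np.allclose(prof.p_down + prof.p_up + prof.p_unpaired, 1.0)


class TestMatchScore:
    defaults = MatchScoreParams()

    def test_both_unpaired_hits_alpha2_plus_alpha3(self):
        a = _profile(np.zeros(3), np.zeros(3), np.ones(3))
        rho = match_score_matrix(a, a, self.defaults)
        assert np.allclose(rho, 0.8 * 1.0 + 0.5)

    def test_opposite_pairing_states_floor_at_alpha3(self):
        a = _profile(np.ones(2), np.zeros(2), np.zeros(2))   # downstream
        b = _profile(np.zeros(2), np.ones(2), np.zeros(2))   # upstream
        rho = match_score_matrix(a, b, self.defaults)
        assert np.allclose(rho, 0.5)

    def test_pair_probability_comparison_special_case(self):
        # alpha1 = alpha2 = 1, alpha3 = 0: agreement in the downstream
        # state scores exactly 1
        a = _profile(np.ones(2), np.zeros(2), np.zeros(2))
        rho = match_score_matrix(a, a, MatchScoreParams(1.0, 1.0, 0.0))
        assert np.allclose(rho, 1.0)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_bounds_hold_for_random_profiles(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(1, 8)), int(rng.integers(1, 8))
        params = MatchScoreParams(*rng.uniform(0, 3, 3))
        profs = []
        for n in (n1, n2):
            raw = rng.dirichlet(np.ones(3), size=n)
            profs.append(_profile(raw[:, 0], raw[:, 1], raw[:, 2]))
        rho = match_score_matrix(profs[0], profs[1], params)
        assert (rho >= params.alpha3 - 1e-12).all()
        assert (rho <= max(params.alpha1, params.alpha2) + params.alpha3 + 1e-9).all()


class TestProclivity:
    def test_single_certain_pair_maps_through(self):
        p = np.zeros((6, 6))
        p[1, 4] = 1.0
        co = np.zeros((5, 6))
        co[0, 1] = 1.0   # i=0 ~ k=1
        co[3, 4] = 1.0   # j=3 ~ l=4
        out = proclivity(PairProbabilityMatrix(6, p), _posteriors(co), 0.01)
        assert out[0, 3] == pytest.approx(1.0)
        out[0, 3] = 0.0
        assert not out.any()

    def test_subthreshold_coincidence_gives_zero(self, rng):
        ppm = random_pair_matrix(rng, 7)
        co = np.full((6, 7), 0.009)
        out = proclivity(ppm, _posteriors(co), cutoff=0.01)
        assert not out.any()

    def test_cutoff_zero_matches_direct_triple_sum(self, rng):
        ppm = random_pair_matrix(rng, 7)
        co = rng.uniform(0, 1, (6, 7))
        out = proclivity(ppm, _posteriors(co), cutoff=0.0)
        ref = np.zeros((6, 6))
        for i in range(6):
            for j in range(i + 1, 6):
                for k in range(7):
                    for l in range(k + 1, 7):
                        ref[i, j] += ppm.p[k, l] * co[i, k] * co[j, l]
        assert np.allclose(out, ref, atol=1e-12)

    def test_cutoff_is_an_approximation_not_semantics(self, rng):
        ppm = random_pair_matrix(rng, 9)
        co = rng.uniform(0, 1, (8, 9)) * rng.uniform(0, 1, (8, 9))
        full = proclivity(ppm, _posteriors(co), cutoff=0.0)
        cut = proclivity(ppm, _posteriors(co), cutoff=0.01)
        diff = np.abs(full - cut).sum()
        assert diff <= 0.01 * max(co.shape) ** 2
        # the cutoff only ever removes mass
        assert (full - cut >= -1e-12).all()


class TestExtrinsic:
    def test_identical_pair_contributes_nothing(self, rng):
        mat = np.triu(rng.uniform(0, 1, (5, 5)), k=1)
        out = extrinsic_information(0, {1: mat}, {1: 1.0}, n_target=5)
        assert not out.any()

    def test_max_normalization(self):
        mat = np.zeros((4, 4))
        mat[0, 3] = 0.7
        out = extrinsic_information(0, {1: mat}, {1: 0.4}, n_target=4)
        assert out[0, 3] == pytest.approx(1.0)

    def test_matches_direct_weighted_sum(self, rng):
        m1 = np.triu(rng.uniform(0, 1, (5, 5)), k=1)
        m2 = np.triu(rng.uniform(0, 1, (5, 5)), k=1)
        psi = {1: 0.3, 2: 0.8}
        ref = 0.7 * m1 + 0.2 * m2
        ref /= ref.max()
        out = extrinsic_information(0, {1: m1, 2: m2}, psi, n_target=5)
        assert np.allclose(out, ref, atol=1e-12)

    def test_permutation_equivariance_in_homologs(self, rng):
        mats = {i: np.triu(rng.uniform(0, 1, (6, 6)), k=1) for i in (1, 2, 3)}
        psi = {1: 0.2, 2: 0.5, 3: 0.9}
        a = extrinsic_information(0, mats, psi, n_target=6)
        perm = {3: mats[1], 1: mats[3], 2: mats[2]}
        psi_p = {3: psi[1], 1: psi[3], 2: psi[2]}
        b = extrinsic_information(0, perm, psi_p, n_target=6)
        assert np.allclose(a, b, atol=1e-12)

    def test_no_homologs_yields_zero(self):
        out = extrinsic_information(0, {}, {}, n_target=3)
        assert out.shape == (3, 3) and not out.any()


def _profile(down, up, unpaired):
    from turboalign.coupling import PairingStateProfile
    return PairingStateProfile(np.asarray(down, float), np.asarray(up, float),
                               np.asarray(unpaired, float))
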