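import numpy as np
import pytest

from turboalign.fixtures import (CANONICAL_PAIRS, FamilySpec,
                                 default_family_spec,
                                 expected_pairwise_identity, generate_family,
                                 mean_pairwise_identity)
from turboalign.io_formats import GAP, RnaSequence, SecondaryStructure


def _tiny_spec(**kw):
    seq = RnaSequence("t", "GGGGGAAAACCCCCAAAA")
    struct = SecondaryStructure(
        18, frozenset({(1, 14), (2, 13), (3, 12), (4, 11), (5, 10)}))
    defaults = dict(seed_sequence=seq, seed_structure=struct, n_seqs=3,
                    rng_seed=3)
    defaults.update(kw)
    return FamilySpec(**defaults)


class TestGenerateFamily:
    def test_zero_rates_give_identical_copies(self):
        spec = _tiny_spec(sub_rate=0.0, indel_rate=0.0)
        seqs, aln, structs = generate_family(spec)
        assert len({s.residues for s in seqs}) == 1
        assert GAP not in "".join(row for _, row in aln.rows)
        assert all(s.pairs == spec.seed_structure.pairs for s in structs)

    def test_fully_compensatory_keeps_pairs_canonical(self):
        spec = _tiny_spec(sub_rate=0.5, compensatory_frac=1.0, indel_rate=0.0,
                          n_seqs=6)
        seqs, _, structs = generate_family(spec)
        for seq, struct in zip(seqs, structs):
            assert len(struct.pairs) == len(spec.seed_structure.pairs)
            for i, j in struct.pairs:
                assert seq.residues[i - 1] + seq.residues[j - 1] \
                    in CANONICAL_PAIRS

    def test_degapping_invariant(self):
        seqs, aln, _ = generate_family(default_family_spec(4))
        for s in seqs:
            assert aln.degapped(s.id) == s.residues

    def test_true_structure_pairs_map_through_alignment(self):
        """With fully compensatory stems, every descendant's pairs land on
        the same alignment-column pairs: structure is conserved through the
        true alignment even as sequences diverge."""
        spec = default_family_spec(6)
        seqs, aln, structs = generate_family(spec)
        colpairs = []
        for s, struct in zip(seqs, structs):
            row = aln.row(s.id)
            col_of = {}
            pos = 0
            for c, ch in enumerate(row):
                if ch != GAP:
                    pos += 1
                    col_of[pos] = c
            colpairs.append({(col_of[i], col_of[j]) for i, j in struct.pairs})
        assert all(cp == colpairs[0] for cp in colpairs[1:])
        assert len(colpairs[0]) == len(spec.seed_structure.pairs)

    def test_determinism_and_seed_sensitivity(self):
        a1 = generate_family(default_family_spec(7))[0]
        a2 = generate_family(default_family_spec(7))[0]
        b = generate_family(default_family_spec(8))[0]
        assert [s.residues for s in a1] == [s.residues for s in a2]
        assert [s.residues for s in a1] != [s.residues for s in b]

    def test_structural_insert_adds_a_hairpin_to_one_descendant(self):
        spec = default_family_spec(11, structural_insert_in=1)
        plain = default_family_spec(11)
        seqs, _, structs = generate_family(spec)
        pseqs, _, pstructs = generate_family(plain)
        assert seqs[1].length > pseqs[1].length
        extra = len(structs[1].pairs) - len(pstructs[1].pairs)
        assert extra == 5  # the inserted 5-bp stem
        for seq, struct in zip(seqs, structs):
            for i, j in struct.pairs:
                assert seq.residues[i - 1] + seq.residues[j - 1] \
                    in CANONICAL_PAIRS

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError, match="rates"):
            _tiny_spec(sub_rate=1.5)


class TestIdentityExpectation:
    def test_realized_identity_near_analytic_expectation(self):
        """Spec'd check: 20 paired + 30 unpaired positions, substitution
        rate 0.3, fully compensatory, no indels."""
        rng = np.random.default_rng(7)
        stem = "".join(
            CANONICAL_PAIRS[i] for i in rng.integers(0, 6, 10))
        pairs = frozenset({(i + 1, 50 - i) for i in range(10)})
        residues = ([stem[2 * i] for i in range(10)]
                    + ["ACGU"[i] for i in rng.integers(0, 4, 30)]
                    + [stem[2 * i + 1] for i in range(9, -1, -1)])
        spec = FamilySpec(
            seed_sequence=RnaSequence("t", "".join(residues)),
            seed_structure=SecondaryStructure(50, pairs),
            n_seqs=12, sub_rate=0.3, compensatory_frac=1.0, indel_rate=0.0,
            rng_seed=7)
        _, aln, _ = generate_family(spec)
        realized = mean_pairwise_identity(aln)
        assert realized == pytest.approx(expected_pairwise_identity(spec),
                                         abs=0.1)

    def test_default_conditions_sit_near_half_identity(self):
        spec = default_family_spec(1)
        assert 0.4 < expected_pairwise_identity(spec) < 0.65
        _, aln, _ = generate_family(spec)
        assert 0.35 < mean_pairwise_identity(aln) < 0.7

    def test_raising_substitution_rate_lowers_expected_identity(self):
        lo = _tiny_spec(sub_rate=0.1)
        hi = _tiny_spec(sub_rate=0.6)
        assert expected_pairwise_identity(hi) < expected_pairwise_identity(lo)
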