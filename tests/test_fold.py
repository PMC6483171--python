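"""MFE and partition-function dynamic programs vs exhaustive enumeration."""

import math
import random

import pytest

from dimerfold.core import RnaSequence
from dimerfold.fold import ConstraintError, fold_mfe, partition_function
from oracles import oracle_fold


def random_sequences(n_seqs, min_len, max_len, seed):
    rng = random.Random(seed)
    return ["".join(rng.choice("ACGU") for _ in range(rng.randint(min_len,
                                                                  max_len)))
            for _ in range(n_seqs)]


class TestAgainstEnumeration:
    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_mfe_partition_and_pair_probs(self, params, seed):
        for s in random_sequences(25, 6, 13, seed):
            seq = RnaSequence("t", s)
            mfe_o, z_o, probs_o = oracle_fold(s, params)
            res = partition_function(seq, params)
            assert res.mfe == pytest.approx(mfe_o, abs=1e-9)
            z_dp = math.exp(-res.ensemble_free_energy / params.rt)
            assert z_dp == pytest.approx(z_o, rel=1e-6)
            n = len(s)
            for i in range(1, n + 1):
                for j in range(i + 1, n + 1):
                    assert res.pair_probability[i, j] == pytest.approx(
                        probs_o.get((i, j), 0.0), abs=1e-9)

    def test_mfe_structure_energy_consistent(self, params):
        from dimerfold.energy import energy_of_structure
        for s in random_sequences(20, 8, 13, seed=77):
            seq = RnaSequence("t", s)
            res = fold_mfe(seq, params)
            assert energy_of_structure(seq, res.mfe_structure, params) == \
                pytest.approx(res.mfe, abs=1e-9)


class TestEdgeCases:
    def test_unpairable_sequence(self, params):
        res = fold_mfe(RnaSequence("a", "AAAAAAAA"), params)
        assert res.mfe == 0.0 and not res.mfe_structure.pairs
        pf = partition_function(RnaSequence("a", "AAAA"), params)
        assert pf.ensemble_free_energy == pytest.approx(0.0)

    def test_single_residue(self, params):
        res = partition_function(RnaSequence("a", "G"), params)
        assert res.mfe == 0.0 and res.ensemble_free_energy == 0.0

    def test_rna_i_hairpin_loop_of_six(self, params, study):
        res = fold_mfe(study["RNA_I"], params)
        loops = res.mfe_structure.hairpin_loops()
        assert len(loops) == 1
        i, j = loops[0]
        assert j - i - 1 == 6

    def test_deterministic(self, params):
        seq = RnaSequence("t", "GGGAAAACCCGGGAAAACCC")
        r1, r2 = fold_mfe(seq, params), fold_mfe(seq, params)
        assert r1.mfe_structure == r2.mfe_structure and r1.mfe == r2.mfe


class TestProperties:
    def test_ensemble_below_mfe(self, params):
        for s in random_sequences(15, 8, 14, seed=5):
            res = partition_function(RnaSequence("t", s), params)
            assert res.ensemble_free_energy <= res.mfe + 1e-9

    def test_pair_probability_rows_sum_below_one(self, params):
        res = partition_function(RnaSequence("t", "GGGGAAAACCCCGAAAC"),
                                 params)
        P = res.pair_probability
        n = len(res.sequence)
        for i in range(1, n + 1):
            total = sum(P[min(i, j), max(i, j)] for j in range(1, n + 1)
                        if j != i)
            assert -1e-12 <= total <= 1.0 + 1e-9

    def test_forcing_unpaired_never_lowers_free_energy(self, params):
        rng = random.Random(99)
        for s in random_sequences(10, 8, 13, seed=31):
            seq = RnaSequence("t", s)
            base = partition_function(seq, params).ensemble_free_energy
            mask = [rng.random() > 0.25 for _ in s]
            constrained = partition_function(
                seq, params, constraints=mask).ensemble_free_energy
            assert constrained >= base - 1e-9


class TestConstraints:
    def test_mask_respected(self, params):
        seq = RnaSequence("t", "GGGGAAAACCCC")
        mask = [False] * len(seq)
        res = fold_mfe(seq, params, constraints=mask)
        assert not res.mfe_structure.pairs and res.mfe == 0.0

    def test_mask_length_mismatch(self, params):
        with pytest.raises(ConstraintError):
            fold_mfe(RnaSequence("t", "GGGAAACCC"), params,
                     constraints=[True] * 4)

    def test_pseudo_energy_against_enumeration(self, params):
        rng = random.Random(4)
        for s in random_sequences(8, 7, 12, seed=8):
            seq = RnaSequence("t", s)
            pseudo = [round(rng.uniform(-0.3, 1.2), 3) for _ in s]
            mfe_o, z_o, _ = oracle_fold(s, params, pseudo=pseudo)
            res = partition_function(seq, params, pseudo=pseudo)
            assert res.mfe == pytest.approx(mfe_o, abs=1e-9)
            assert math.exp(-res.ensemble_free_energy / params.rt) == \
                pytest.approx(z_o, rel=1e-6)
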