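"""Homodimer cofolding: nick rules, sentinels, and the dimerization gap."""

import math
import random

import pytest

from dimerfold.cofold import (cofold_homodimer, dimer_partition_function,
                              _monomer_hairpin_z)
from dimerfold.core import RnaSequence
from oracles import enumerate_structures, oracle_fold
from dimerfold.energy import pair_set_energy


class TestAgainstEnumeration:
    @pytest.mark.parametrize("seed", [21, 22])
    def test_dimer_partition_function(self, params, seed):
        rng = random.Random(seed)
        for _ in range(12):
            n = rng.randint(4, 8)
            s1 = "".join(rng.choice("ACGU") for _ in range(n))
            z_mono, z_inter = dimer_partition_function(
                RnaSequence("t", s1), params)
            _, z_mono_o, _ = oracle_fold(s1, params)
            _, z_inter_o, _ = oracle_fold(s1 + s1, params, nick=n,
                                          require_spanning=True)
            assert z_mono == pytest.approx(z_mono_o, rel=1e-9)
            assert z_inter == pytest.approx(z_inter_o, rel=1e-9)

    def test_perfect_duplex_gap_strongly_negative(self, params):
        seq = RnaSequence("g", "GGGGCCCC")
        eq = cofold_homodimer(seq, params)
        _, z_inter_o, _ = oracle_fold(seq.residues * 2, params, nick=8,
                                      require_spanning=True)
        expected = (-params.rt * math.log(z_inter_o) + params.duplex_init
                    + params.symmetry_correction)
        assert eq.dimer_f == pytest.approx(expected, rel=1e-9)
        assert eq.gap < -10.0


class TestSentinelsAndInvariants:
    def test_non_dimerizing_sequence(self, params):
        eq = cofold_homodimer(RnaSequence("a", "AAAA"), params)
        assert math.isinf(eq.gap) and eq.gap > 0
        assert eq.k_dimer == 0.0 and not eq.dimerizing

    def test_gap_equilibrium_identity(self, params, study):
        eq = cofold_homodimer(study["RNA_II"], params)
        assert eq.gap == pytest.approx(eq.dimer_f - 2 * eq.monomer_f)
        assert eq.k_dimer == pytest.approx(math.exp(-eq.gap / params.rt))

    def test_strand_relabeling_symmetry(self, params):
        # swapping the two strand labels (i <-> i+n mod 2n) is an
        # energy-preserving bijection of the dimer structure set
        s1 = "GACGUC"
        n = len(s1)
        s = s1 + s1
        total = swapped = 0.0
        for pairs in enumerate_structures(s, nick=n):
            if not any(i <= n < j for i, j in pairs):
                continue
            e = pair_set_energy(s, pairs, params, nick=n)
            total += math.exp(-e / params.rt)
            relabeled = frozenset(
                tuple(sorted(((i + n - 1) % (2 * n) + 1,
                              (j + n - 1) % (2 * n) + 1)))
                for i, j in pairs)
            e2 = pair_set_energy(s, relabeled, params, nick=n)
            swapped += math.exp(-e2 / params.rt)
        assert swapped == pytest.approx(total, rel=1e-9)

    def test_symmetry_correction_switch(self, study):
        from dimerfold.params import load_parameters
        on = cofold_homodimer(study["RNA_II"], load_parameters())
        off = cofold_homodimer(study["RNA_II"],
                               load_parameters(symmetry_correction=False))
        rt = load_parameters().rt
        assert on.dimer_f - off.dimer_f == pytest.approx(rt * math.log(2))


class TestHairpinRestrictedEnsemble:
    def test_matches_filtered_enumeration(self, params):
        rng = random.Random(17)
        for _ in range(8):
            n = rng.randint(6, 11)
            s = "".join(rng.choice("ACGU") for _ in range(n))
            z = _monomer_hairpin_z(s, params)
            z_o = 0.0
            for pairs in enumerate_structures(s):
                if not pairs:
                    continue
                ordered = sorted(pairs)
                chain = all(ordered[k][0] < ordered[k + 1][0]
                            and ordered[k + 1][1] < ordered[k][1]
                            for k in range(len(ordered) - 1))
                if chain:
                    z_o += math.exp(-pair_set_energy(s, pairs, params)
                                    / params.rt)
            assert z == pytest.approx(z_o, rel=1e-9)

    def test_flag_changes_monomer_reference(self, params, study):
        all_ens = cofold_homodimer(study["RNA_I"], params)
        hp = cofold_homodimer(study["RNA_I"], params,
                              monomer_ensemble="hairpin")
        assert hp.dimer_f == pytest.approx(all_ens.dimer_f)
        assert hp.monomer_f >= all_ens.monomer_f  # restricted ensemble

    def test_length_validation(self, params):
        with pytest.raises(ValueError):
            cofold_homodimer(RnaSequence("x", "A"), params)
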