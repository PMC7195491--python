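import math

import numpy as np
import pytest

from negcon.evo import (
    EvoFilterParams,
    evaluate_evo_filter,
    evaluate_profiles,
    identity_condition,
    property_difference,
    shannon_entropy,
    size_difference,
)
from negcon.msa import ALPHABET, FrequencyProfile

from conftest import make_msa, make_profile, random_profile

# Independent classification tables for the brute-force oracle (written out
# by hand, not imported from the implementation).
ORACLE_PROPERTY = {}
for aa in "IVLMFWACGP":
    ORACLE_PROPERTY[aa] = "hydrophobic"
for aa in "STQNHY":
    ORACLE_PROPERTY[aa] = "polar"
for aa in "KR":
    ORACLE_PROPERTY[aa] = "positive"
for aa in "ED":
    ORACLE_PROPERTY[aa] = "negative"

ORACLE_SIZE = {}
for rank, group in enumerate(["GAS", "CDPNT", "EVQH", "MILKR", "FYW"]):
    for aa in group:
        ORACLE_SIZE[aa] = rank

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def oracle_property_difference(pi: FrequencyProfile, pj: FrequencyProfile) -> float:
    total = 0.0
    for k in AA20:
        for l in AA20:
            if ORACLE_PROPERTY[k] != ORACLE_PROPERTY[l]:
                total += pi.frequency(k) * pj.frequency(l) * 100.0
    return total


def oracle_size_difference(pi: FrequencyProfile, pj: FrequencyProfile) -> float:
    larger = smaller = 0.0
    for k in AA20:
        for l in AA20:
            w = pi.frequency(k) * pj.frequency(l) * 100.0
            if ORACLE_SIZE[k] > ORACLE_SIZE[l]:
                larger += w
            elif ORACLE_SIZE[k] < ORACLE_SIZE[l]:
                smaller += w
    return max(larger, smaller)


class TestShannonEntropy:
    def test_single_symbol_is_zero(self):
        assert shannon_entropy(make_profile({"A": 1.0})) == 0.0

    def test_uniform_over_21_is_one(self):
        prof = FrequencyProfile(0, np.full(21, 1 / 21), 21)
        assert shannon_entropy(prof) == pytest.approx(1.0, abs=1e-12)

    def test_two_state_column_below_conservation_cutoff(self):
        s = shannon_entropy(make_profile({"A": 0.5, "V": 0.5}))
        assert s == pytest.approx(math.log(2) / math.log(21), abs=1e-12)
        assert s < 0.23

    def test_invalid_profile_rejected(self):
        prof = make_profile({"A": 1.0})
        object.__setattr__(prof, "freqs", prof.freqs * 0.5)
        with pytest.raises(ValueError, match="sum"):
            shannon_entropy(prof)

    def test_permutation_invariant(self, rng):
        freqs = rng.dirichlet(np.ones(21))
        a = FrequencyProfile(0, freqs, 50)
        b = FrequencyProfile(0, rng.permutation(freqs), 50)
        assert shannon_entropy(a) == pytest.approx(shannon_entropy(b), abs=1e-12)

    def test_merging_equal_symbols_never_increases(self):
        split = make_profile({"A": 0.25, "V": 0.25, "K": 0.5})
        merged = make_profile({"A": 0.5, "K": 0.5})
        assert shannon_entropy(merged) <= shannon_entropy(split)


class TestIdentityCondition:
    def test_conserved_and_different_accepted(self):
        assert identity_condition(make_profile({"A": 1.0}), make_profile({"S": 1.0}))

    def test_same_identity_rejected(self):
        assert not identity_condition(make_profile({"A": 1.0}), make_profile({"A": 1.0}))

    def test_tied_modes_disjoint_rule(self):
        # 50/50 A/V has S ≈ 0.2277 < 0.23 and tied modes {A, V}, disjoint from {S}
        pi = make_profile({"A": 0.5, "V": 0.5})
        assert identity_condition(pi, make_profile({"S": 1.0}))
        # overlapping tied modes are not "different in identity"
        assert not identity_condition(pi, make_profile({"A": 1.0}))

    def test_unconserved_column_rejected(self):
        noisy = FrequencyProfile(0, np.full(21, 1 / 21), 21)
        assert not identity_condition(noisy, make_profile({"S": 1.0}))


class TestPropertyDifference:
    def test_opposite_charges_full_difference(self):
        assert property_difference(make_profile({"K": 1.0}), make_profile({"E": 1.0})) == 100.0

    def test_same_group_zero(self):
        assert property_difference(make_profile({"K": 1.0}), make_profile({"R": 1.0})) == 0.0

    def test_mixed_profiles(self):
        pi = make_profile({"K": 0.5, "R": 0.5})
        pj = make_profile({"E": 0.95, "K": 0.05})
        assert property_difference(pi, pj) == pytest.approx(95.0, abs=1e-12)

    def test_gap_contributes_to_no_pair(self):
        pi = make_profile({"K": 0.5, "-": 0.5})
        assert property_difference(pi, make_profile({"E": 1.0})) == pytest.approx(50.0)

    def test_renormalized_variant_restores_full_scale(self):
        pi = make_profile({"K": 0.5, "-": 0.5})
        pj = make_profile({"E": 1.0})
        assert property_difference(pi, pj, renormalize_gaps=True) == pytest.approx(100.0)


class TestSizeDifference:
    def test_tiny_vs_bulky_full_difference(self):
        assert size_difference(make_profile({"G": 1.0}), make_profile({"W": 1.0})) == 100.0

    def test_same_size_group_zero(self):
        assert size_difference(make_profile({"L": 1.0}), make_profile({"I": 1.0})) == 0.0

    def test_split_directions_do_not_add(self):
        pi = make_profile({"G": 0.5, "W": 0.5})
        pj = make_profile({"E": 1.0})
        # W larger than E gives 50; G smaller than E gives 50; max = 50 < 90
        assert size_difference(pi, pj) == pytest.approx(50.0, abs=1e-12)


class TestAgainstBruteForceOracle:
    def test_property_and_size_match_naive_enumeration(self, rng):
        for _ in range(300):
            pi = random_profile(rng)
            pj = random_profile(rng)
            assert property_difference(pi, pj) == pytest.approx(
                oracle_property_difference(pi, pj), abs=1e-12)
            assert size_difference(pi, pj) == pytest.approx(
                oracle_size_difference(pi, pj), abs=1e-12)

    def test_symmetry_in_profile_exchange(self, rng):
        for _ in range(300):
            pi = random_profile(rng)
            pj = random_profile(rng)
            assert property_difference(pi, pj) == pytest.approx(
                property_difference(pj, pi), abs=1e-12)
            assert size_difference(pi, pj) == pytest.approx(
                size_difference(pj, pi), abs=1e-12)

    def test_concentrated_profiles_give_zero_or_hundred(self, rng):
        for aa_i in "AKEWG":
            for aa_j in "SLDFY":
                v = property_difference(make_profile({aa_i: 1.0}),
                                        make_profile({aa_j: 1.0}))
                assert v in (0.0, 100.0)


class TestEvaluateEvoFilter:
    def test_conserved_charge_swap_accepted(self):
        msa_i = make_msa(["K", "K", "K"], subgroup="i")
        msa_j = make_msa(["E", "E", "E"], subgroup="j")
        v = evaluate_evo_filter(msa_i, msa_j, 1)
        assert v.identity_condition
        assert v.property_percent == 100.0
        assert v.accepted

    def test_identical_conserved_columns_rejected(self):
        msa = make_msa(["Q", "Q", "Q"])
        v = evaluate_evo_filter(msa, make_msa(["Q", "Q"], subgroup="j"), 1)
        assert not v.accepted

    def test_near_uniform_columns_rejected(self, rng):
        # high-entropy columns: no condition can hold at default cutoffs
        rows_i = ["".join(rng.choice(list(ALPHABET), 1)) for _ in range(40)]
        rows_j = ["".join(rng.choice(list(ALPHABET), 1)) for _ in range(40)]
        v = evaluate_evo_filter(make_msa(rows_i), make_msa(rows_j, subgroup="j"), 1)
        assert v.entropy_i > 0.23 and v.entropy_j > 0.23
        assert not v.identity_condition
        assert v.property_percent < 90 and v.size_percent < 90
        assert not v.accepted

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            evaluate_evo_filter(make_msa(["AA"]), make_msa(["A"], subgroup="j"), 1)

    def test_verdict_is_disjunction_of_conditions(self, rng):
        params = EvoFilterParams()
        for _ in range(100):
            pi = random_profile(rng)
            pj = random_profile(rng)
            v = evaluate_profiles(pi, pj, 1, "i", "j", params)
            expected = (
                v.identity_condition
                or v.property_percent > params.property_cutoff
                or v.size_percent > params.size_cutoff
            )
            assert v.accepted == expected

    def test_raising_cutoffs_never_accepts_a_rejected_position(self, rng):
        base = EvoFilterParams()
        stricter = EvoFilterParams(entropy_cutoff=0.15, property_cutoff=99.0,
                                   size_cutoff=99.0)
        for _ in range(200):
            pi = random_profile(rng)
            pj = random_profile(rng)
            v_base = evaluate_profiles(pi, pj, 1, "i", "j", base)
            v_hard = evaluate_profiles(pi, pj, 1, "i", "j", stricter)
            if not v_base.accepted:
                assert not v_hard.accepted
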