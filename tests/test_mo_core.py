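"""Pairwise MO, overlap matrices and community summaries against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabolic_overlap import (
    Community,
    CommunityMember,
    GenomeAnnotation,
    ReactantProfile,
    ValidationError,
    community_mo,
    overlap_matrix,
    overlap_matrix_from_profiles,
    pairwise_mo,
    reactant_profile,
    restrict_to_subsystem,
    summarize_community,
)
from metabolic_overlap.mo_core import (
    OverlapMatrix,
    load_overlap_matrix,
    save_overlap_matrix,
)

from conftest import make_metadata


def brute_force_mo(a: frozenset, b: frozenset) -> int:
    """Independent oracle: count common members by explicit membership loop."""
    count = 0
    for compound in a:
        if compound in b:
            count += 1
    return count


def random_profiles(rng, n_genomes, universe_size=60):
    universe = [f"c{i}" for i in range(universe_size)]
    profiles = []
    for g in range(n_genomes):
        k = int(rng.integers(0, universe_size))
        members = rng.choice(universe, size=k, replace=False)
        profiles.append(ReactantProfile(f"g{g}", frozenset(members)))
    return profiles


class TestReactantProfile:
    def test_full_denitrifier_profile(self, nitrogen_db, full_denitrifier):
        profile = reactant_profile(full_denitrifier, nitrogen_db)
        assert profile.reactants == {"NO3", "NO2", "NO", "N2O"}

    def test_partial_denitrifier_profile(self, nitrogen_db, partial_denitrifier):
        assert reactant_profile(partial_denitrifier, nitrogen_db).reactants == {"NO2", "NO"}

    def test_empty_genome_gives_empty_profile(self, nitrogen_db):
        profile = reactant_profile(GenomeAnnotation("g", frozenset()), nitrogen_db)
        assert profile.reactants == frozenset()

    def test_reversible_reaction_adds_both_sides(self, nitrogen_db):
        profile = reactant_profile(GenomeAnnotation("g", frozenset({"R_rev"})), nitrogen_db)
        assert profile.reactants == {"A", "B"}

    def test_exclusion_list_removes_currency_compounds(self, nitrogen_db, full_denitrifier):
        profile = reactant_profile(full_denitrifier, nitrogen_db, exclude={"NO2"})
        assert profile.reactants == {"NO3", "NO", "N2O"}

    def test_unknown_reaction_ignored_lenient_raises_strict(self, nitrogen_db):
        genome = GenomeAnnotation("g", frozenset({"R_nar", "R_missing"}))
        assert reactant_profile(genome, nitrogen_db).reactants == {"NO3"}
        with pytest.raises(ValidationError, match="R_missing"):
            reactant_profile(genome, nitrogen_db, strict=True)

    def test_union_bound(self, nitrogen_db, full_denitrifier):
        profile = reactant_profile(full_denitrifier, nitrogen_db)
        assert len(profile.reactants) <= sum(
            len(nitrogen_db[rid].substrates) + len(nitrogen_db[rid].products)
            for rid in full_denitrifier.reaction_ids
        )


class TestPairwiseMO:
    def test_denitrification_worked_example(self, nitrogen_db, full_denitrifier,
                                            partial_denitrifier):
        a = reactant_profile(full_denitrifier, nitrogen_db)
        b = reactant_profile(partial_denitrifier, nitrogen_db)
        assert pairwise_mo(a, b) == 2  # the shared utilizable reactants: NO2 and NO

    def test_disjoint_profiles_overlap_zero(self):
        a = ReactantProfile("a", frozenset({"x", "y"}))
        b = ReactantProfile("b", frozenset({"z"}))
        assert pairwise_mo(a, b) == 0

    def test_self_overlap_is_profile_size(self):
        a = ReactantProfile("a", frozenset({"x", "y", "z"}))
        assert pairwise_mo(a, a) == 3

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(11)
        profiles = random_profiles(rng, 40)
        for _ in range(1000):
            i, j = rng.integers(0, len(profiles), size=2)
            assert pairwise_mo(profiles[i], profiles[j]) == brute_force_mo(
                profiles[i].reactants, profiles[j].reactants
            )


class TestOverlapMatrix:
    def test_worked_example_matrix(self, nitrogen_db, denitrifier_community):
        matrix = overlap_matrix(denitrifier_community, nitrogen_db)
        assert matrix.genome_ids == ("org1", "org2")
        assert matrix.values[0, 1] == matrix.values[1, 0] == 2
        assert tuple(matrix.diagonal) == (4, 2)

    def test_identical_genomes_give_constant_matrix(self, nitrogen_db):
        profile = ReactantProfile("g", frozenset({"a", "b", "c"}))
        profiles = [ReactantProfile(f"g{i}", profile.reactants) for i in range(4)]
        matrix = overlap_matrix_from_profiles(profiles)
        assert (matrix.values == 3).all()

    def test_entrywise_equality_with_oracle_30_genomes(self):
        rng = np.random.default_rng(23)
        profiles = random_profiles(rng, 30)
        matrix = overlap_matrix_from_profiles(profiles)
        for i in range(30):
            for j in range(30):
                assert matrix.values[i, j] == brute_force_mo(
                    profiles[i].reactants, profiles[j].reactants
                )

    def test_single_genome_rejected(self):
        with pytest.raises(ValidationError):
            overlap_matrix_from_profiles([ReactantProfile("g", frozenset({"a"}))])

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValidationError, match="symmetric"):
            OverlapMatrix(("a", "b"), np.array([[1, 2], [0, 1]]))

    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        matrix = overlap_matrix_from_profiles(random_profiles(rng, 5))
        path = tmp_path / "matrix.tsv"
        save_overlap_matrix(matrix, path)
        reloaded = load_overlap_matrix(path)
        assert reloaded.genome_ids == matrix.genome_ids
        assert np.array_equal(reloaded.values, matrix.values)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_invariants_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        profiles = random_profiles(rng, int(rng.integers(2, 12)), universe_size=30)
        matrix = overlap_matrix_from_profiles(profiles)
        values, diag = matrix.values, matrix.diagonal
        assert np.array_equal(values, values.T)
        assert all(diag[i] == len(profiles[i]) for i in range(len(profiles)))
        for i in range(len(profiles)):
            for j in range(len(profiles)):
                assert values[i, j] <= min(diag[i], diag[j])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_monotone_under_reaction_addition(self, nitrogen_db, seed):
        rng = np.random.default_rng(seed)
        all_rxns = sorted(nitrogen_db.reactions)
        base = frozenset(rng.choice(all_rxns, size=2, replace=False))
        other = GenomeAnnotation("other", frozenset(rng.choice(all_rxns, size=3, replace=False)))
        grown = frozenset(all_rxns)  # superset of base
        p_other = reactant_profile(other, nitrogen_db)
        mo_before = pairwise_mo(reactant_profile(GenomeAnnotation("g", base), nitrogen_db), p_other)
        mo_after = pairwise_mo(reactant_profile(GenomeAnnotation("g", grown), nitrogen_db), p_other)
        assert mo_after >= mo_before


class TestCommunityMO:
    def test_two_genome_matrix_median_is_single_pair(self, nitrogen_db, denitrifier_community):
        matrix = overlap_matrix(denitrifier_community, nitrogen_db)
        assert community_mo(matrix) == 2

    def test_median_and_mean_over_off_diagonal(self):
        values = np.array([[5, 1, 2], [1, 6, 9], [2, 9, 7]])
        matrix = OverlapMatrix(("a", "b", "c"), values)
        assert community_mo(matrix, "median") == 2
        assert community_mo(matrix, "mean") == 4

    def test_diagonal_never_enters_the_statistic(self):
        values = np.array([[100, 1], [1, 100]])
        assert community_mo(OverlapMatrix(("a", "b"), values)) == 1


class TestSummarizeCommunity:
    @staticmethod
    def _community(sizes, reaction_sets, nitrogen_db):
        members = tuple(
            CommunityMember(
                GenomeAnnotation(f"g{i}", reaction_sets[i]),
                make_metadata(f"g{i}", size=sizes[i]),
            )
            for i in range(len(sizes))
        )
        return Community("s1", "marine", members)

    def test_normalization_arithmetic(self, nitrogen_db):
        sets = [frozenset({"R_nar", "R_nir", "R_nor", "R_nos"})] * 3
        community = self._community([2_500_000, 3_000_000, 3_500_000], sets, nitrogen_db)
        summary = summarize_community(community, nitrogen_db)
        assert summary.median_genome_size_bp == 3_000_000
        assert summary.normalized_mo == summary.mo_central / 3_000_000
        assert summary.mo_central == 4  # identical genomes share all 4 reactants

    def test_doubling_sizes_halves_normalized_mo(self, nitrogen_db):
        sets = [frozenset({"R_nar"}), frozenset({"R_nar", "R_nir"})]
        small = self._community([2_000_000, 4_000_000], sets, nitrogen_db)
        big = self._community([4_000_000, 8_000_000], sets, nitrogen_db)
        s_small = summarize_community(small, nitrogen_db)
        s_big = summarize_community(big, nitrogen_db)
        assert s_big.mo_central == s_small.mo_central
        assert s_big.normalized_mo == pytest.approx(s_small.normalized_mo / 2)

    def test_summary_recomputable_from_matrix(self, nitrogen_db, denitrifier_community):
        summary = summarize_community(denitrifier_community, nitrogen_db)
        matrix = overlap_matrix(denitrifier_community, nitrogen_db)
        import statistics

        assert summary.mo_central == float(np.median(matrix.off_diagonal_values()))
        expected_size = statistics.median(denitrifier_community.genome_sizes_bp)
        assert summary.normalized_mo == summary.mo_central / expected_size


def test_subsystem_restricted_mo_never_exceeds_full_mo(nitrogen_db):
    rng = np.random.default_rng(17)
    all_rxns = sorted(nitrogen_db.reactions)
    for _ in range(50):
        a = GenomeAnnotation("a", frozenset(rng.choice(all_rxns, size=3, replace=False)))
        b = GenomeAnnotation("b", frozenset(rng.choice(all_rxns, size=3, replace=False)))
        full = pairwise_mo(reactant_profile(a, nitrogen_db), reactant_profile(b, nitrogen_db))
        ra = restrict_to_subsystem(a, nitrogen_db, "Nitrogen")
        rb = restrict_to_subsystem(b, nitrogen_db, "Nitrogen")
        sub = pairwise_mo(reactant_profile(ra, nitrogen_db), reactant_profile(rb, nitrogen_db))
        assert sub <= full
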