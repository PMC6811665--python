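"""Determinism, referential integrity and planted structure of the generators."""

import filecmp
import math
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from metabolic_overlap import (
    ConfigError,
    GenomeAnnotation,
    SimulationConfig,
    classify_pathway,
    cophenetic_matrix,
    denitrification_pathway,
    evolve_genomes,
    generate_metadata,
    generate_reaction_db,
    generate_survey,
    generate_tree,
    overlap_matrix_from_profiles,
    pairwise_mo,
    plant_denitrification,
    reactant_profile,
)
from metabolic_overlap.synthetic_data import add_denitrification_reactions


class TestGenerateReactionDB:
    def test_same_seed_identical(self):
        config = SimulationConfig(n_compounds=50, n_reactions=100, root_repertoire_size=50)
        assert generate_reaction_db(config, seed=7).reactions == \
            generate_reaction_db(config, seed=7).reactions

    def test_referential_integrity(self):
        db = generate_reaction_db(SimulationConfig(), seed=1)
        for rxn in db.reactions.values():
            assert (rxn.substrates | rxn.products) <= set(db.compounds)

    def test_dimensions_and_subsystem_round_robin(self):
        config = SimulationConfig(n_compounds=50, n_reactions=26, root_repertoire_size=20)
        db = generate_reaction_db(config, seed=2)
        assert len(db.reactions) == 26
        assert len(db.subsystems) == 13  # 26 reactions cycle twice through 13 labels

    def test_substrate_count_exceeding_compounds_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_compounds=2, substrates_per_reaction=(1, 5))

    def test_reversible_fraction_within_binomial_tolerance(self):
        # ~20% reversible: pooled over 20 seeds, the observed fraction should
        # sit within 4 binomial standard errors of the design value
        total, reversible = 0, 0
        config = SimulationConfig(n_compounds=60, n_reactions=100, root_repertoire_size=50)
        for seed in range(20):
            db = generate_reaction_db(config, seed=seed)
            total += len(db.reactions)
            reversible += sum(r.direction == "reversible" for r in db.reactions.values())
        p_hat = reversible / total
        se = math.sqrt(0.2 * 0.8 / total)
        assert abs(p_hat - 0.2) < 4 * se


class TestGenerateTree:
    def test_two_tips_parseable(self):
        dmat = cophenetic_matrix(generate_tree(2, seed=1))
        assert len(dmat) == 2

    def test_same_seed_identical_text(self):
        assert generate_tree(15, seed=9) == generate_tree(15, seed=9)

    def test_single_tip_rejected(self):
        with pytest.raises(ConfigError):
            generate_tree(1, seed=0)

    def test_cophenetic_satisfies_triangle_inequality(self):
        for seed in range(50):
            dmat = cophenetic_matrix(generate_tree(8, seed=seed))
            d = dmat.values
            n = len(dmat)
            for i in range(n):
                for j in range(n):
                    for k in range(n):
                        assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestEvolveGenomes:
    def test_zero_rates_leave_all_tips_identical(self):
        config = SimulationConfig(gain_rate=0.0, loss_rate=0.0, n_reactions=100,
                                  n_compounds=80, root_repertoire_size=40)
        db = generate_reaction_db(config, seed=3)
        genomes = evolve_genomes(generate_tree(10, seed=4), db, config, seed=5)
        repertoires = {g.reaction_ids for g in genomes}
        assert len(repertoires) == 1
        profiles = [reactant_profile(g, db) for g in genomes]
        matrix = overlap_matrix_from_profiles(profiles)
        assert len(set(matrix.off_diagonal_values())) == 1

    def test_randomizing_rates_approach_independence(self):
        # when each branch's flip probability 1-exp(-rate*L) is near 1/2 the
        # child's presence is nearly independent of the parent, so two tips
        # approach independent repertoires: expected reaction-set overlap of
        # sets of sizes a, b over R reactions is a*b/R
        config = SimulationConfig(
            gain_rate=0.7, loss_rate=0.7, mean_branch_length=1.0,
            n_reactions=200, n_compounds=150, root_repertoire_size=100,
        )
        db = generate_reaction_db(config, seed=6)
        observed, expected = [], []
        for seed in range(10):
            tree = generate_tree(2, seed=seed, mean_branch_length=config.mean_branch_length)
            genomes = evolve_genomes(tree, db, config, seed=seed + 50)
            a, b = (g.reaction_ids for g in genomes)
            a, b = set(a), set(b)
            observed.append(len(a & b))
            expected.append(len(a) * len(b) / config.n_reactions)
        assert np.mean(observed) == pytest.approx(np.mean(expected), rel=0.2)

    def test_default_rates_plant_distance_decay(self):
        config = SimulationConfig(n_tips=20)
        db = generate_reaction_db(config, seed=7)
        negative = 0
        for seed in range(10):
            tree = generate_tree(20, seed=seed)
            genomes = evolve_genomes(tree, db, config, seed=seed + 100)
            profiles = [reactant_profile(g, db) for g in genomes]
            order = {g.genome_id: i for i, g in enumerate(genomes)}
            dmat = cophenetic_matrix(tree, tip_subset=[g.genome_id for g in genomes])
            mos, dists = [], []
            for i in range(len(genomes)):
                for j in range(i + 1, len(genomes)):
                    mos.append(pairwise_mo(profiles[i], profiles[j]))
                    dists.append(dmat.values[i, j])
            if stats.spearmanr(dists, mos).statistic < 0:
                negative += 1
        assert negative >= 9

    def test_seeded_evolution_reproducible(self):
        config = SimulationConfig(n_reactions=60, n_compounds=50, root_repertoire_size=30)
        db = generate_reaction_db(config, seed=8)
        tree = generate_tree(6, seed=9)
        assert evolve_genomes(tree, db, config, seed=10) == \
            evolve_genomes(tree, db, config, seed=10)


class TestPlantDenitrification:
    @pytest.fixture
    def planted_setup(self):
        config = SimulationConfig(n_reactions=60, n_compounds=50, root_repertoire_size=30)
        db = add_denitrification_reactions(generate_reaction_db(config, seed=11))
        pathway = denitrification_pathway(db)
        genomes = evolve_genomes(generate_tree(10, seed=12), db, config, seed=13)
        return config, db, pathway, genomes

    def test_exact_fractions_recovered(self, planted_setup):
        config, db, pathway, genomes = planted_setup
        planted = plant_denitrification(genomes, pathway, config, seed=14)
        calls = [classify_pathway(g, pathway).status for g in planted]
        assert calls.count("complete") == 3   # 0.3 * 10
        assert calls.count("partial") == 2    # 0.2 * 10
        assert calls.count("absent") == 5

    def test_all_complete(self, planted_setup):
        config, db, pathway, genomes = planted_setup
        from dataclasses import replace

        cfg = replace(config, frac_complete_denitrifiers=1.0, frac_partial_denitrifiers=0.0)
        planted = plant_denitrification(genomes, pathway, cfg, seed=15)
        assert all(classify_pathway(g, pathway).status == "complete" for g in planted)

    def test_all_absent(self, planted_setup):
        config, db, pathway, genomes = planted_setup
        from dataclasses import replace

        cfg = replace(config, frac_complete_denitrifiers=0.0, frac_partial_denitrifiers=0.0)
        planted = plant_denitrification(genomes, pathway, cfg, seed=16)
        assert all(classify_pathway(g, pathway).status == "absent" for g in planted)

    def test_non_pathway_reactions_untouched(self, planted_setup):
        config, db, pathway, genomes = planted_setup
        planted = plant_denitrification(genomes, pathway, config, seed=17)
        pathway_rxns = pathway.all_reaction_ids
        for before, after in zip(genomes, planted):
            assert before.reaction_ids - pathway_rxns == after.reaction_ids - pathway_rxns


class TestGenerateMetadata:
    def test_zero_noise_size_proportional(self):
        from dataclasses import replace

        config = replace(SimulationConfig(), size_noise_sd=0.0)
        genomes = [
            GenomeAnnotation(f"g{i}", frozenset(f"r{j}" for j in range(k)))
            for i, k in enumerate([10, 20, 30])
        ]
        metadata = generate_metadata(genomes, config, "s1", "marine", seed=18)
        assert [m.genome_size_bp for m in metadata] == [100_000, 200_000, 300_000]

    def test_completeness_in_reported_range(self):
        config = SimulationConfig()
        genomes = [
            GenomeAnnotation(f"g{i}", frozenset({"r"}))
            for i in range(200)
        ]
        metadata = generate_metadata(genomes, config, "s1", "marine", seed=19)
        assert all(50.0 <= m.completeness_pct <= 100.0 for m in metadata)


class TestGenerateSurvey:
    def test_bundle_files_byte_identical_across_runs(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        generate_survey(n_studies=3, seed=20, outdir=a, tips_range=(5, 8))
        generate_survey(n_studies=3, seed=20, outdir=b, tips_range=(5, 8))
        for rel in ("reactions.tsv", "annotations.tsv", "metadata.tsv", "manifest.json"):
            assert filecmp.cmp(a / rel, b / rel, shallow=False), rel
        for tree in sorted((a / "trees").glob("*.nwk")):
            assert filecmp.cmp(tree, b / "trees" / tree.name, shallow=False)

    def test_bundle_loads_through_every_reader(self, tmp_path):
        from metabolic_overlap import (
            group_into_communities,
            load_genome_annotations,
            load_genome_metadata,
            load_reaction_db,
        )

        bundle = generate_survey(n_studies=3, seed=21, outdir=tmp_path, tips_range=(5, 8))
        db = load_reaction_db(bundle.paths["reaction_db"])
        genomes = load_genome_annotations(bundle.paths["annotations"], db=db)
        metadata = load_genome_metadata(bundle.paths["metadata"])
        communities = group_into_communities(genomes, metadata)
        assert len(communities) == 3
        assert {g.genome_id: g.reaction_ids for g in genomes} == \
            {g.genome_id: g.reaction_ids for g in bundle.annotations}
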