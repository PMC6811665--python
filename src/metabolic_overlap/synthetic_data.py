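"""Synthetic reaction universes, trees and communities with planted structure.

Real surveys of metagenome-assembled genomes need external downloads and
annotation services; this module generates stand-ins with the statistical
structure the analysis assumes, so every pipeline stage is testable offline:

* a random reaction database over a closed compound universe, with subsystem
  labels assigned round-robin over the 13 shipped metabolism categories;
* random binary trees (sequential random pairwise joins, exponential branch
  lengths);
* genomes evolved along the tree under an independent per-reaction two-state
  gain/loss Markov process — presence is lost along a branch of length L with
  probability 1 - exp(-loss_rate * L) and gained with 1 - exp(-gain_rate * L).
  Nearby tips therefore share more of their repertoire, planting the
  distance-decay of overlap the association tests are meant to detect;
* planted denitrifier fractions (largest-remainder rounding, so small
  communities hit the requested counts exactly);
* genome sizes proportional to repertoire size plus Gaussian noise, and
  completeness drawn uniformly on [50, 100] — the range reported for real
  MAG collections.

Every generator is deterministic given its seed; ``generate_survey`` produces
a full multi-study bundle (database, annotations, metadata, per-study trees)
and can write it to disk in the exact dialects the loaders consume, with a
manifest recording paths and the seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .annotations import SUBSYSTEM_CATEGORIES, GenomeAnnotation, GenomeMetadata
from .errors import ConfigError
from .pathway_completeness import (
    DENITRIFICATION_STEP_COMPOUNDS,
    PathwayDefinition,
    denitrification_pathway,
)
from .reaction_db import Reaction, ReactionDB

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic universe.

    Defaults are sized so that one community resembles a modest MAG study:
    a few hundred reactions/compounds, 30 genomes, repertoires of ~150
    reactions at the root eroding along the tree, genome sizes of a few Mbp
    proportional to repertoire size, and normalized MO landing in the
    1e-6 .. 1e-4 compounds/bp range typical of real communities.
    """

    n_compounds: int = 300
    n_reactions: int = 400
    substrates_per_reaction: tuple[int, int] = (1, 3)  # inclusive range
    products_per_reaction: tuple[int, int] = (1, 3)
    reversible_fraction: float = 0.2
    n_tips: int = 30
    mean_branch_length: float = 0.1
    gain_rate: float = 0.05   # events per unit branch length
    loss_rate: float = 0.3
    root_repertoire_size: int = 150
    bp_per_reaction: float = 10_000.0
    size_noise_sd: float = 100_000.0
    frac_complete_denitrifiers: float = 0.3
    frac_partial_denitrifiers: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "n_compounds": self.n_compounds,
            "n_reactions": self.n_reactions,
            "n_tips": self.n_tips,
            "root_repertoire_size": self.root_repertoire_size,
            "bp_per_reaction": self.bp_per_reaction,
            "mean_branch_length": self.mean_branch_length,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive (got {value})")
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ConfigError("gain_rate and loss_rate must be >= 0")
        if self.size_noise_sd < 0:
            raise ConfigError("size_noise_sd must be >= 0")
        for name, (lo, hi) in (
            ("substrates_per_reaction", self.substrates_per_reaction),
            ("products_per_reaction", self.products_per_reaction),
        ):
            if lo < 1 or hi < lo:
                raise ConfigError(f"{name} must be a 1-based inclusive range (got {(lo, hi)})")
            if hi > self.n_compounds:
                raise ConfigError(f"{name} upper bound exceeds n_compounds")
        fracs = (self.frac_complete_denitrifiers, self.frac_partial_denitrifiers)
        if any(f < 0 for f in fracs) or sum(fracs) > 1.0:
            raise ConfigError("denitrifier fractions must be >= 0 and sum to <= 1")
        if self.root_repertoire_size > self.n_reactions:
            raise ConfigError("root_repertoire_size cannot exceed n_reactions")


def _compound_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"cpd{i:0{width}d}" for i in range(1, n + 1)]


def generate_reaction_db(config: SimulationConfig, seed: int | None = None) -> ReactionDB:
    """Random reaction database over a closed compound universe.

    Substrate and product sets are sampled without replacement (disjoint
    within a reaction); ~``reversible_fraction`` of reactions are reversible;
    subsystem labels cycle round-robin through the 13 shipped categories.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    compounds = _compound_ids(config.n_compounds)
    width = len(str(config.n_reactions))
    reactions = []
    for i in range(config.n_reactions):
        n_sub = int(rng.integers(config.substrates_per_reaction[0],
                                 config.substrates_per_reaction[1] + 1))
        n_prod = int(rng.integers(config.products_per_reaction[0],
                                  config.products_per_reaction[1] + 1))
        picks = rng.choice(config.n_compounds, size=n_sub + n_prod, replace=False)
        direction = "reversible" if rng.random() < config.reversible_fraction else "forward"
        reactions.append(
            Reaction(
                reaction_id=f"rxn{i + 1:0{width}d}",
                substrates=frozenset(compounds[k] for k in picks[:n_sub]),
                products=frozenset(compounds[k] for k in picks[n_sub:]),
                direction=direction,
                subsystems=frozenset({SUBSYSTEM_CATEGORIES[i % len(SUBSYSTEM_CATEGORIES)]}),
            )
        )
    return ReactionDB.from_reactions(reactions)


def generate_tree(
    n_tips: int,
    seed: int | None = None,
    mean_branch_length: float = 0.1,
    tip_prefix: str = "g",
) -> str:
    """Random binary tree by sequential random pairwise joins; newick text.

    Tips are labelled ``g1..gN`` (or with another prefix); every branch gets
    an exponential length with the given mean, formatted to 6 decimals so the
    output is byte-stable across runs with one seed.
    """
    if n_tips < 2:
        raise ConfigError(f"a tree needs >= 2 tips (got {n_tips})")
    rng = np.random.default_rng(seed)
    nodes = [f"{tip_prefix}{i + 1}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        bl_left = rng.exponential(mean_branch_length)
        bl_right = rng.exponential(mean_branch_length)
        nodes.append(f"({left}:{bl_left:.6f},{right}:{bl_right:.6f})")
    return nodes[0] + ";"


def evolve_genomes(
    tree: str,
    db: ReactionDB,
    config: SimulationConfig,
    seed: int | None = None,
) -> list[GenomeAnnotation]:
    """Evolve reaction repertoires along a tree under gain/loss dynamics.

    The root receives a uniform random repertoire of ``root_repertoire_size``
    reactions; along each branch, each present reaction is lost with
    probability 1 - exp(-loss_rate * L) and each absent one gained with
    1 - exp(-gain_rate * L), independently.  One annotation per tip, in the
    tree's tip order.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tree_obj = dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)
    reaction_ids = np.array(sorted(db.reactions))
    n = len(reaction_ids)
    if config.root_repertoire_size > n:
        raise ConfigError("root_repertoire_size exceeds the database size")

    root_presence = np.zeros(n, dtype=bool)
    root_presence[rng.choice(n, size=config.root_repertoire_size, replace=False)] = True
    tree_obj.seed_node.presence = root_presence

    annotations: list[GenomeAnnotation] = []
    for node in tree_obj.preorder_node_iter():
        if node is tree_obj.seed_node:
            pass
        else:
            length = node.edge.length or 0.0
            p_loss = 1.0 - math.exp(-config.loss_rate * length)
            p_gain = 1.0 - math.exp(-config.gain_rate * length)
            parent = node.parent_node.presence
            draws = rng.random(n)
            node.presence = np.where(parent, draws >= p_loss, draws < p_gain)
        if node.is_leaf():
            annotations.append(
                GenomeAnnotation(
                    node.taxon.label,
                    frozenset(reaction_ids[node.presence]),
                )
            )
    return annotations


def _largest_remainder_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer apportionment of n into len(fractions) parts, largest remainder."""
    quotas = [f * n for f in fractions]
    counts = [int(math.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    by_frac = sorted(range(len(quotas)), key=lambda i: (quotas[i] - counts[i]), reverse=True)
    for i in by_frac[:remainder]:
        counts[i] += 1
    return counts


def plant_denitrification(
    genomes: Sequence[GenomeAnnotation],
    pathway: PathwayDefinition,
    config: SimulationConfig,
    seed: int | None = None,
) -> list[GenomeAnnotation]:
    """Overwrite pathway content so known denitrifier fractions hold exactly.

    ``frac_complete_denitrifiers`` of the genomes receive one qualifying
    reaction per step; ``frac_partial_denitrifiers`` receive a random proper
    non-empty subset of steps; the rest are purged of all pathway reactions.
    Counts use largest-remainder rounding; assignment order is a seeded
    shuffle; original genome order is preserved in the output.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = len(genomes)
    fracs = (
        config.frac_complete_denitrifiers,
        config.frac_partial_denitrifiers,
        1.0 - config.frac_complete_denitrifiers - config.frac_partial_denitrifiers,
    )
    n_complete, n_partial, _ = _largest_remainder_counts(n, fracs)

    all_pathway_rxns = pathway.all_reaction_ids
    step_choices = [sorted(step.reaction_ids) for step in pathway.steps]
    order = rng.permutation(n)
    out = list(genomes)
    for rank, idx in enumerate(order):
        genome = genomes[idx]
        base = genome.reaction_ids - all_pathway_rxns
        if rank < n_complete:
            added = {choices[int(rng.integers(len(choices)))] for choices in step_choices}
        elif rank < n_complete + n_partial:
            k = int(rng.integers(1, len(pathway.steps)))  # proper non-empty subset
            picked = rng.choice(len(pathway.steps), size=k, replace=False)
            added = {
                step_choices[s][int(rng.integers(len(step_choices[s])))] for s in picked
            }
        else:
            added = set()
        out[idx] = GenomeAnnotation(genome.genome_id, frozenset(base | added))
    return out


def generate_metadata(
    genomes: Sequence[GenomeAnnotation],
    config: SimulationConfig,
    study_id: str,
    ecosystem: str,
    seed: int | None = None,
) -> list[GenomeMetadata]:
    """Sizes proportional to repertoire (plus noise) and uniform completeness.

    ``genome_size_bp = round(bp_per_reaction * |reactions| + N(0, size_noise_sd))``
    floored at 1; ``completeness_pct ~ Uniform[50, 100)``, the range reported
    for real MAG collections.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records = []
    for genome in genomes:
        noise = rng.normal(0.0, config.size_noise_sd) if config.size_noise_sd > 0 else 0.0
        size = max(1, round(config.bp_per_reaction * len(genome.reaction_ids) + noise))
        completeness = float(rng.uniform(50.0, 100.0))
        records.append(
            GenomeMetadata(
                genome_id=genome.genome_id,
                study_id=study_id,
                ecosystem=ecosystem,
                genome_size_bp=size,
                completeness_pct=completeness,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Multi-study survey bundles.

DEFAULT_ECOSYSTEMS = (
    "marine", "freshwater", "soil", "animal", "built", "engineered",
)


@dataclass
class SurveyBundle:
    """An in-memory multi-study survey plus (optionally) its on-disk paths."""

    config: SimulationConfig
    seed: int
    db: ReactionDB
    annotations: list[GenomeAnnotation]
    metadata: list[GenomeMetadata]
    trees: dict[str, str]  # study_id -> newick
    paths: dict[str, str] = field(default_factory=dict)


def generate_survey(
    n_studies: int = 6,
    config: SimulationConfig | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
    tips_range: tuple[int, int] = (6, 24),
    plant_richness_effect: bool = True,
    plant_pathway: bool = True,
) -> SurveyBundle:
    """One call producing a survey every other module can run on.

    Studies share one reaction database but evolve on independent trees with
    study-specific tip counts.  With ``plant_richness_effect``, the root
    repertoire shrinks as richness grows (richer communities overlap less), a
    programmed negative richness-MO dependence.  With ``plant_pathway``,
    denitrifier fractions from the config are planted in every study.
    Writing to ``outdir`` emits the native TSV/newick dialects plus a JSON
    manifest; the same seed yields byte-identical files.
    """
    config = config or SimulationConfig()
    master = np.random.default_rng(seed)

    def child_seed() -> int:
        return int(master.integers(0, 2**31 - 1))

    db = generate_reaction_db(config, seed=child_seed())
    pathway = None
    if plant_pathway:
        # the random universe uses opaque compound ids, so the canonical
        # nitrogen-cycle reactions are added explicitly to make the pathway
        # expressible before planting denitrifier fractions
        db = add_denitrification_reactions(db)
        pathway = denitrification_pathway(db)

    annotations: list[GenomeAnnotation] = []
    metadata: list[GenomeMetadata] = []
    trees: dict[str, str] = {}
    for s in range(1, n_studies + 1):
        study_id = f"s{s}"
        ecosystem = DEFAULT_ECOSYSTEMS[(s - 1) % len(DEFAULT_ECOSYSTEMS)]
        n_tips = int(master.integers(tips_range[0], tips_range[1] + 1))
        if plant_richness_effect:
            root_size = max(40, config.root_repertoire_size - 6 * (n_tips - tips_range[0]))
        else:
            root_size = config.root_repertoire_size
        study_cfg = replace(config, n_tips=n_tips, root_repertoire_size=root_size)
        tree = generate_tree(
            n_tips, seed=child_seed(),
            mean_branch_length=config.mean_branch_length,
            tip_prefix=f"{study_id}_g",
        )
        genomes = evolve_genomes(tree, db, study_cfg, seed=child_seed())
        if pathway is not None:
            genomes = plant_denitrification(genomes, pathway, study_cfg, seed=child_seed())
        annotations.extend(genomes)
        metadata.extend(
            generate_metadata(genomes, study_cfg, study_id, ecosystem, seed=child_seed())
        )
        trees[study_id] = tree

    bundle = SurveyBundle(
        config=config, seed=seed, db=db,
        annotations=annotations, metadata=metadata, trees=trees,
    )
    if outdir is not None:
        write_survey(bundle, outdir)
    return bundle


def add_denitrification_reactions(db: ReactionDB) -> ReactionDB:
    """Extend a database with the four canonical denitrification reactions."""
    extra = [
        Reaction(
            reaction_id=f"rxn_denit{i + 1}",
            substrates=frozenset({sub}),
            products=frozenset({prod}),
            direction="forward",
            subsystems=frozenset({"Nitrogen"}),
        )
        for i, (_, (sub, prod)) in enumerate(DENITRIFICATION_STEP_COMPOUNDS)
    ]
    return ReactionDB.from_reactions(list(db.reactions.values()) + extra)


def write_survey(bundle: SurveyBundle, outdir: str | Path) -> dict[str, str]:
    """Write a bundle in the dialects the loaders consume, plus a manifest."""
    from .annotations import save_genome_annotations, save_genome_metadata
    from .reaction_db import save_reaction_db

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "trees").mkdir(exist_ok=True)

    paths = {
        "reaction_db": str(outdir / "reactions.tsv"),
        "annotations": str(outdir / "annotations.tsv"),
        "metadata": str(outdir / "metadata.tsv"),
    }
    save_reaction_db(bundle.db, paths["reaction_db"])
    save_genome_annotations(bundle.annotations, paths["annotations"])
    save_genome_metadata(bundle.metadata, paths["metadata"])
    for study_id in sorted(bundle.trees):
        tree_path = outdir / "trees" / f"{study_id}.nwk"
        tree_path.write_text(bundle.trees[study_id] + "\n")
        paths[f"tree:{study_id}"] = str(tree_path)

    # manifest paths are relative to the bundle directory so that two bundles
    # generated with one seed are byte-identical wherever they are written
    rel_paths = {k: str(Path(v).relative_to(outdir)) for k, v in paths.items()}
    manifest = {"seed": bundle.seed, "paths": rel_paths}
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = str(manifest_path)
    bundle.paths = paths
    return paths
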