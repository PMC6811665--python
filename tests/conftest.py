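"""Shared fixtures: the toy nitrogen universe and small synthetic bundles."""

import pytest

from metabolic_overlap import (
    Community,
    CommunityMember,
    GenomeAnnotation,
    GenomeMetadata,
    Reaction,
    ReactionDB,
)

# The four denitrification reduction steps, nitrate to dinitrogen.
DENIT_REACTIONS = (
    ("R_nar", "NO3", "NO2"),
    ("R_nir", "NO2", "NO"),
    ("R_nor", "NO", "N2O"),
    ("R_nos", "N2O", "N2"),
)


@pytest.fixture(scope="session")
def nitrogen_db() -> ReactionDB:
    """Toy database: the four denitrification reactions plus two distractors."""
    reactions = [
        Reaction(rid, frozenset({sub}), frozenset({prod}), "forward", frozenset({"Nitrogen"}))
        for rid, sub, prod in DENIT_REACTIONS
    ]
    reactions.append(
        Reaction("R_sox", frozenset({"H2S"}), frozenset({"SO4"}), "forward",
                 frozenset({"Sulfur"}))
    )
    reactions.append(
        Reaction("R_rev", frozenset({"A"}), frozenset({"B"}), "reversible", frozenset())
    )
    return ReactionDB.from_reactions(reactions)


@pytest.fixture
def full_denitrifier() -> GenomeAnnotation:
    """Organism 1: performs all four reduction steps (NO3 to N2)."""
    return GenomeAnnotation("org1", frozenset({"R_nar", "R_nir", "R_nor", "R_nos"}))


@pytest.fixture
def partial_denitrifier() -> GenomeAnnotation:
    """Organism 2: only reduces NO2 to N2O (two middle steps)."""
    return GenomeAnnotation("org2", frozenset({"R_nir", "R_nor"}))


@pytest.fixture
def denitrifier_community(full_denitrifier, partial_denitrifier) -> Community:
    members = []
    for i, ann in enumerate((full_denitrifier, partial_denitrifier)):
        members.append(
            CommunityMember(
                ann,
                GenomeMetadata(ann.genome_id, "study1", "marine", 3_000_000 + i, 90.0),
            )
        )
    return Community("study1", "marine", tuple(members))


def make_metadata(genome_id, study_id="s1", ecosystem="marine",
                  size=3_000_000, completeness=90.0) -> GenomeMetadata:
    return GenomeMetadata(genome_id, study_id, ecosystem, size, completeness)
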