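"""Metabolic overlap: reactant profiles, overlap matrices, community summaries.

The metabolic overlap (MO) between two genomes is the number of compounds both
can *utilize* — the size of the intersection of their reactant profiles, where
a reactant profile is the union of consumed-side compounds over all reactions
the genome encodes.  Counting shared reactants rather than shared reactions
deliberately credits organisms that reach the same substrate through different
enzymatic routes.

A community's overlap structure is stored densely as a symmetric genome x
genome integer matrix whose diagonal holds each genome's own profile size.
The community-level MO is the median (or mean) over the n(n-1)/2 unique
off-diagonal pairs; dividing by the community's median genome size (bp) gives
the genome-size-normalized MO in compounds per base pair, the unit used to
compare communities of very different organism sizes.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Collection, Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .annotations import Community, GenomeAnnotation
from .errors import ValidationError
from .reaction_db import ReactionDB, reactant_set

logger = logging.getLogger(__name__)

Statistic = Literal["median", "mean"]


@dataclass(frozen=True)
class ReactantProfile:
    """A genome's utilizable-compound set."""

    genome_id: str
    reactants: frozenset[str]

    def __len__(self) -> int:
        return len(self.reactants)


@dataclass
class OverlapMatrix:
    """Symmetric genome x genome matrix of MO counts for one community."""

    genome_ids: tuple[str, ...]
    values: np.ndarray  # square, dtype int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n = len(self.genome_ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} genome ids"
            )
        if not np.array_equal(self.values, self.values.T):
            raise ValidationError("overlap matrix must be symmetric")
        if (self.values < 0).any():
            raise ValidationError("overlap counts must be non-negative")

    def __len__(self) -> int:
        return len(self.genome_ids)

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.values)

    def off_diagonal_values(self) -> np.ndarray:
        """The n(n-1)/2 unique pairwise MO counts (strict upper triangle)."""
        iu = np.triu_indices(len(self.genome_ids), k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genome_ids, columns=self.genome_ids)


def reactant_profile(
    annotation: GenomeAnnotation,
    db: ReactionDB,
    strict: bool = False,
    exclude: Collection[str] = (),
    reversible_both_sides: bool = True,
) -> ReactantProfile:
    """Union of utilizable reactants over a genome's reactions.

    Reaction ids absent from the database are skipped (with a warning) unless
    ``strict`` is set, in which case they raise.  ``exclude`` removes currency
    compounds (water, protons, ...) from the profile when a caller opts in.
    """
    reactants: set[str] = set()
    unknown: list[str] = []
    for rid in annotation.reaction_ids:
        rxn = db.reactions.get(rid)
        if rxn is None:
            unknown.append(rid)
            continue
        reactants |= reactant_set(rxn, reversible_both_sides=reversible_both_sides)
    if unknown:
        if strict:
            raise ValidationError(
                f"genome {annotation.genome_id!r}: unresolvable reaction id(s): {sorted(unknown)}"
            )
        logger.warning(
            "genome %s: %d reaction id(s) not in database, ignored",
            annotation.genome_id, len(unknown),
        )
    if exclude:
        reactants -= set(exclude)
    return ReactantProfile(annotation.genome_id, frozenset(reactants))


def pairwise_mo(a: ReactantProfile, b: ReactantProfile) -> int:
    """MO(a, b): number of compounds utilizable by both genomes."""
    return len(a.reactants & b.reactants)


def overlap_matrix_from_profiles(profiles: Sequence[ReactantProfile]) -> OverlapMatrix:
    n = len(profiles)
    if n < 2:
        raise ValidationError(f"overlap matrix needs >= 2 genomes (got {n})")
    values = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        values[i, i] = len(profiles[i])
        for j in range(i + 1, n):
            mo = pairwise_mo(profiles[i], profiles[j])
            values[i, j] = mo
            values[j, i] = mo
    return OverlapMatrix(tuple(p.genome_id for p in profiles), values)


def overlap_matrix(
    community: Community,
    db: ReactionDB,
    strict: bool = False,
    exclude: Collection[str] = (),
    reversible_both_sides: bool = True,
) -> OverlapMatrix:
    """All pairwise MO values for one community, in member order."""
    profiles = [
        reactant_profile(
            ann, db, strict=strict, exclude=exclude,
            reversible_both_sides=reversible_both_sides,
        )
        for ann in community.annotations
    ]
    return overlap_matrix_from_profiles(profiles)


def community_mo(matrix: OverlapMatrix, statistic: Statistic = "median") -> float:
    """Central MO over the unique off-diagonal pairs (diagonal excluded)."""
    if len(matrix) < 2:
        raise ValidationError("community MO needs a matrix over >= 2 genomes")
    pairs = matrix.off_diagonal_values()
    if statistic == "median":
        return float(np.median(pairs))
    if statistic == "mean":
        return float(np.mean(pairs))
    raise ValueError(f"unknown statistic {statistic!r}")


@dataclass(frozen=True)
class CommunitySummary:
    """Per-study aggregate of community overlap."""

    study_id: str
    ecosystem: str
    n_genomes: int
    mo_central: float
    median_genome_size_bp: float
    normalized_mo: float  # compounds per bp

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ValidationError("a community summary needs >= 2 genomes")


def summarize_community(
    community: Community,
    db: ReactionDB,
    statistic: Statistic = "median",
    **profile_kwargs,
) -> CommunitySummary:
    """Central MO and its genome-size normalization for one community.

    ``normalized_mo = mo_central / median(genome_size_bp)`` exactly, in
    compounds per base pair.
    """
    matrix = overlap_matrix(community, db, **profile_kwargs)
    mo_central = community_mo(matrix, statistic=statistic)
    median_size = float(statistics.median(community.genome_sizes_bp))
    return CommunitySummary(
        study_id=community.study_id,
        ecosystem=community.ecosystem,
        n_genomes=len(community),
        mo_central=mo_central,
        median_genome_size_bp=median_size,
        normalized_mo=mo_central / median_size,
    )


# ---------------------------------------------------------------------------
# TSV I/O: matrices as square labelled tables, summaries one row per community.

def save_overlap_matrix(matrix: OverlapMatrix, path: str | Path) -> None:
    matrix.to_dataframe().to_csv(path, sep="\t", index_label="genome_id")


def load_overlap_matrix(path: str | Path) -> OverlapMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: matrix rows and columns must carry identical ids")
    return OverlapMatrix(tuple(str(g) for g in df.index), df.to_numpy())


SUMMARY_COLUMNS = (
    "study_id", "ecosystem", "n_genomes", "mo_central",
    "median_genome_size_bp", "normalized_mo",
)


def save_community_summaries(summaries: Iterable[CommunitySummary], path: str | Path) -> None:
    rows = [
        {
            "study_id": s.study_id,
            "ecosystem": s.ecosystem,
            "n_genomes": s.n_genomes,
            "mo_central": f"{s.mo_central:.10g}",
            "median_genome_size_bp": f"{s.median_genome_size_bp:.10g}",
            "normalized_mo": f"{s.normalized_mo:.10g}",
        }
        for s in summaries
    ]
    pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS)).to_csv(path, sep="\t", index=False)


def load_community_summaries(path: str | Path) -> list[CommunitySummary]:
    df = pd.read_csv(path, sep="\t", dtype={"study_id": str, "ecosystem": str})
    return [
        CommunitySummary(
            study_id=row.study_id,
            ecosystem=row.ecosystem,
            n_genomes=int(row.n_genomes),
            mo_central=float(row.mo_central),
            median_genome_size_bp=float(row.median_genome_size_bp),
            normalized_mo=float(row.normalized_mo),
        )
        for row in df.itertuples(index=False)
    ]
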