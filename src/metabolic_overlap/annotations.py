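"""Genome annotations, metadata, completeness filtering and community grouping.

The package ingests the *output* of an annotation pipeline (gene calling, role
assignment, role-to-reaction mapping) as a long-format table of
(genome, reaction) pairs; it never calls genes or remote annotation services
itself.  Genome metadata carries the study (= community) key, an ecosystem
label, the assembly size in base pairs and the predicted completeness
percentage, mirroring what genome-quality tools report for
metagenome-assembled genomes.

Communities are studies with at least two member genomes; singleton studies
are excluded from all pairwise analyses (an overlap needs a pair).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import TableFormatError, ValidationError
from .reaction_db import ReactionDB, open_text

logger = logging.getLogger(__name__)

#: The 13 metabolism subsystem categories used for subsystem-restricted overlap.
#: User-supplied databases may carry any labels; this list is the shipped default
#: used by the synthetic generator and the survey report ordering.
SUBSYSTEM_CATEGORIES: tuple[str, ...] = (
    "Amino Acid",
    "Aromatic",
    "Carbohydrates",
    "Cofactors",
    "Fatty acids",
    "Nitrogen",
    "Nucleoside",
    "Nucleotide sugars",
    "Phosphorus",
    "Protein",
    "Respiration",
    "Secondary Metabolism",
    "Sulfur",
)

ANNOTATION_COLUMNS = ("genome_id", "reaction_id")
METADATA_COLUMNS = ("genome_id", "study_id", "ecosystem", "genome_size_bp", "completeness_pct")


@dataclass(frozen=True)
class GenomeAnnotation:
    """A genome identifier bound to its (deduplicated) reaction id set."""

    genome_id: str
    reaction_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValidationError("genome_id must be non-empty")


@dataclass(frozen=True)
class GenomeMetadata:
    genome_id: str
    study_id: str
    ecosystem: str
    genome_size_bp: int
    completeness_pct: float

    def __post_init__(self) -> None:
        if self.genome_size_bp <= 0:
            raise ValidationError(
                f"genome {self.genome_id!r}: genome_size_bp must be positive "
                f"(got {self.genome_size_bp})"
            )
        if not 0.0 <= self.completeness_pct <= 100.0:
            raise ValidationError(
                f"genome {self.genome_id!r}: completeness_pct must lie in [0, 100] "
                f"(got {self.completeness_pct})"
            )


@dataclass(frozen=True)
class CommunityMember:
    annotation: GenomeAnnotation
    metadata: GenomeMetadata

    @property
    def genome_id(self) -> str:
        return self.annotation.genome_id


@dataclass(frozen=True)
class Community:
    """All genomes recovered in one study, joined with their metadata."""

    study_id: str
    ecosystem: str
    members: tuple[CommunityMember, ...]

    def __post_init__(self) -> None:
        # pairwise analyses need >= 2 members; that rule is enforced by the
        # default grouping threshold, so the container itself only rejects
        # the empty case (min_members=1 legitimately yields singletons)
        if not self.members:
            raise ValidationError(f"community {self.study_id!r} has no members")
        if any(m.metadata.study_id != self.study_id for m in self.members):
            raise ValidationError(f"community {self.study_id!r}: member from a different study")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def genome_ids(self) -> tuple[str, ...]:
        return tuple(m.genome_id for m in self.members)

    @property
    def annotations(self) -> tuple[GenomeAnnotation, ...]:
        return tuple(m.annotation for m in self.members)

    @property
    def genome_sizes_bp(self) -> tuple[int, ...]:
        return tuple(m.metadata.genome_size_bp for m in self.members)


def load_genome_annotations(
    path: str | Path,
    db: ReactionDB | None = None,
    strict: bool = False,
) -> list[GenomeAnnotation]:
    """Read a long-format (genome_id, reaction_id) TSV into per-genome reaction sets.

    When a :class:`ReactionDB` is supplied, rows citing unknown reaction ids are
    warned about and, under ``strict=True``, dropped (lenient default keeps
    them: MAG annotations routinely cite deprecated ids).
    """
    path = Path(path)
    with open_text(path) as handle:
        df = pd.read_csv(handle, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s): {missing}")

    by_genome: dict[str, set[str]] = defaultdict(set)
    n_unknown = 0
    for row in df.itertuples(index=False):
        gid = str(row.genome_id).strip()
        rid = str(row.reaction_id).strip()
        if not gid or not rid:
            continue
        if db is not None and rid not in db:
            n_unknown += 1
            if strict:
                continue
        by_genome[gid].add(rid)
    if n_unknown:
        action = "dropped" if strict else "kept"
        logger.warning(
            "%s: %d row(s) referenced reaction ids absent from the database (%s)",
            path, n_unknown, action,
        )
    annotations = [
        GenomeAnnotation(gid, frozenset(rids)) for gid, rids in by_genome.items() if rids
    ]
    logger.info("%s: loaded %d genome annotation(s)", path, len(annotations))
    return annotations


def save_genome_annotations(genomes: Iterable[GenomeAnnotation], path: str | Path) -> None:
    rows = [
        {"genome_id": g.genome_id, "reaction_id": rid}
        for g in sorted(genomes, key=lambda g: g.genome_id)
        for rid in sorted(g.reaction_ids)
    ]
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(path, sep="\t", index=False)


def load_genome_metadata(path: str | Path) -> list[GenomeMetadata]:
    """Read and validate the genome metadata TSV."""
    path = Path(path)
    with open_text(path) as handle:
        df = pd.read_csv(handle, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s): {missing}")

    records: list[GenomeMetadata] = []
    for idx, row in df.iterrows():
        try:
            size = int(float(row["genome_size_bp"]))
            completeness = float(row["completeness_pct"])
        except (TypeError, ValueError) as exc:
            raise TableFormatError(
                f"{path} row {idx + 2}: non-numeric genome_size_bp/completeness_pct"
            ) from exc
        records.append(
            GenomeMetadata(
                genome_id=str(row["genome_id"]).strip(),
                study_id=str(row["study_id"]).strip(),
                ecosystem=str(row["ecosystem"]).strip(),
                genome_size_bp=size,
                completeness_pct=completeness,
            )
        )
    logger.info("%s: loaded %d metadata record(s)", path, len(records))
    return records


def save_genome_metadata(records: Iterable[GenomeMetadata], path: str | Path) -> None:
    rows = [
        {
            "genome_id": r.genome_id,
            "study_id": r.study_id,
            "ecosystem": r.ecosystem,
            "genome_size_bp": r.genome_size_bp,
            "completeness_pct": f"{r.completeness_pct:.4f}",
        }
        for r in sorted(records, key=lambda r: r.genome_id)
    ]
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(path, sep="\t", index=False)


def _metadata_map(metadata: Iterable[GenomeMetadata] | Mapping[str, GenomeMetadata]) -> dict[str, GenomeMetadata]:
    if isinstance(metadata, Mapping):
        return dict(metadata)
    return {m.genome_id: m for m in metadata}


def filter_by_completeness(
    genomes: Sequence[GenomeAnnotation],
    metadata: Iterable[GenomeMetadata] | Mapping[str, GenomeMetadata],
    min_pct: float,
) -> list[GenomeAnnotation]:
    """Keep genomes whose predicted completeness is >= ``min_pct`` (order preserved)."""
    meta = _metadata_map(metadata)
    orphans = [g.genome_id for g in genomes if g.genome_id not in meta]
    if orphans:
        raise ValidationError(f"genomes without metadata: {sorted(orphans)}")
    kept = [g for g in genomes if meta[g.genome_id].completeness_pct >= min_pct]
    logger.info(
        "completeness filter >= %.1f%%: kept %d of %d genomes", min_pct, len(kept), len(genomes)
    )
    return kept


def group_into_communities(
    genomes: Sequence[GenomeAnnotation],
    metadata: Iterable[GenomeMetadata] | Mapping[str, GenomeMetadata],
    min_members: int = 2,
) -> list[Community]:
    """Partition genomes into per-study communities, dropping small studies.

    Studies with fewer than ``min_members`` genomes (by default, singletons)
    are excluded and logged: a single genome admits no pairwise overlap.
    """
    meta = _metadata_map(metadata)
    orphans = [g.genome_id for g in genomes if g.genome_id not in meta]
    if orphans:
        raise ValidationError(f"genomes without metadata: {sorted(orphans)}")

    by_study: dict[str, list[CommunityMember]] = defaultdict(list)
    for g in genomes:
        by_study[meta[g.genome_id].study_id].append(CommunityMember(g, meta[g.genome_id]))

    communities: list[Community] = []
    n_dropped_studies = 0
    n_dropped_genomes = 0
    for study_id in sorted(by_study):
        members = by_study[study_id]
        if len(members) < min_members:
            n_dropped_studies += 1
            n_dropped_genomes += len(members)
            logger.info(
                "study %s dropped (%d member(s) < min_members=%d)",
                study_id, len(members), min_members,
            )
            continue
        communities.append(
            Community(
                study_id=study_id,
                ecosystem=members[0].metadata.ecosystem,
                members=tuple(members),
            )
        )
    logger.info(
        "grouped %d genomes into %d communities (%d study(ies)/%d genome(s) below threshold)",
        len(genomes), len(communities), n_dropped_studies, n_dropped_genomes,
    )
    return communities


def restrict_to_subsystem(
    annotation: GenomeAnnotation, db: ReactionDB, category: str
) -> GenomeAnnotation:
    """Intersect a genome's reaction set with one subsystem category.

    The match is case-insensitive.  A category carried by no reaction in the
    database raises :class:`ValidationError` — distinguishing a mistyped label
    from a genome that genuinely encodes nothing in that category (which
    yields an empty, but valid, annotation).
    """
    wanted = category.strip().lower()
    in_category = {
        rid
        for rid, rxn in db.reactions.items()
        if any(s.lower() == wanted for s in rxn.subsystems)
    }
    if not in_category:
        raise ValidationError(
            f"subsystem category {category!r} matches no reaction in the database"
        )
    return GenomeAnnotation(annotation.genome_id, annotation.reaction_ids & in_category)


def load_subsystem_assignments(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a reaction_id → subsystem TSV (override mapping for DBs without labels)."""
    path = Path(path)
    with open_text(path) as handle:
        df = pd.read_csv(handle, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in ("reaction_id", "subsystem") if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s): {missing}")
    by_rxn: dict[str, set[str]] = defaultdict(set)
    for row in df.itertuples(index=False):
        if row.reaction_id and row.subsystem:
            by_rxn[str(row.reaction_id).strip()].add(str(row.subsystem).strip())
    return {rid: frozenset(subs) for rid, subs in by_rxn.items()}


def apply_subsystem_assignments(
    db: ReactionDB, assignments: Mapping[str, frozenset[str]]
) -> ReactionDB:
    """Return a new database with subsystem labels replaced by ``assignments``."""
    from dataclasses import replace

    reactions = [
        replace(rxn, subsystems=frozenset(assignments.get(rid, rxn.subsystems)))
        for rid, rxn in db.reactions.items()
    ]
    return ReactionDB.from_reactions(reactions)
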