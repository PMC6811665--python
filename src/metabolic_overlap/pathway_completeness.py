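"""Pathway completeness calls: complete, partial and absent denitrifiers.

Denitrification reduces nitrate stepwise to dinitrogen gas:

    NO3- -> NO2- -> NO -> N2O -> N2        (four reduction steps)

A genome encoding at least one qualifying reaction for *every* step is a
complete denitrifier; one encoding a proper non-empty subset of steps is a
partial denitrifier; a genome with no step at all is absent.  Classification
is reaction-presence based (no gene-copy counting), mirroring how overlap
itself is computed.

Pathway definitions are data, not code: the default four-step denitrification
definition is derived from whichever loaded reaction database by matching each
step's substrate/product compound pair, and any pathway can be supplied as a
(pathway, step, reaction_id) TSV.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotations import Community, GenomeAnnotation
from .errors import TableFormatError, ValidationError
from .reaction_db import ReactionDB, open_text

logger = logging.getLogger(__name__)

#: Step labels and (substrate, product) compound pairs of canonical
#: denitrification, in pathway order.  Compound ids are those used by the
#: native/synthetic databases; override for databases with other id schemes.
DENITRIFICATION_STEP_COMPOUNDS: tuple[tuple[str, tuple[str, str]], ...] = (
    ("nitrate_reduction", ("NO3", "NO2")),
    ("nitrite_reduction", ("NO2", "NO")),
    ("nitric_oxide_reduction", ("NO", "N2O")),
    ("nitrous_oxide_reduction", ("N2O", "N2")),
)


@dataclass(frozen=True)
class PathwayStep:
    label: str
    reaction_ids: frozenset[str]  # any one qualifies the step

    def __post_init__(self) -> None:
        if not self.reaction_ids:
            raise ValidationError(f"pathway step {self.label!r} has an empty reaction set")


@dataclass(frozen=True)
class PathwayDefinition:
    name: str
    steps: tuple[PathwayStep, ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValidationError(f"pathway {self.name!r} has no steps")

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def all_reaction_ids(self) -> frozenset[str]:
        out: set[str] = set()
        for step in self.steps:
            out |= step.reaction_ids
        return frozenset(out)


@dataclass(frozen=True)
class PathwayCall:
    genome_id: str
    status: str  # complete | partial | absent
    steps_present: frozenset[str]


@dataclass(frozen=True)
class DenitrifierSummary:
    """Counts, proportions and complete:partial ratio for one group of genomes."""

    group_id: str
    n_complete: int
    n_partial: int
    n_absent: int
    prop_complete: float
    prop_partial: float
    ratio_complete_to_partial: float  # inf when partial=0<complete; nan when both 0

    @property
    def n_total(self) -> int:
        return self.n_complete + self.n_partial + self.n_absent

    @property
    def ratio_defined(self) -> bool:
        return not math.isnan(self.ratio_complete_to_partial)


def _reaction_matches_step(rxn, substrate: str, product: str) -> bool:
    if substrate in rxn.substrates and product in rxn.products:
        return True
    if rxn.direction == "reversible" and substrate in rxn.products and product in rxn.substrates:
        return True
    return False


def denitrification_pathway(
    db: ReactionDB,
    step_compounds: Sequence[tuple[str, tuple[str, str]]] = DENITRIFICATION_STEP_COMPOUNDS,
) -> PathwayDefinition:
    """Bind the four denitrification steps to a database's reaction ids.

    Each step collects every reaction whose consumed/produced compound pair
    matches the step (either orientation for reversible reactions).  A step
    with no qualifying reaction raises: the database then cannot express the
    pathway at all.
    """
    steps = []
    for label, (substrate, product) in step_compounds:
        qualifying = frozenset(
            rid for rid, rxn in db.reactions.items()
            if _reaction_matches_step(rxn, substrate, product)
        )
        if not qualifying:
            raise ValidationError(
                f"no reaction in the database converts {substrate} to {product} "
                f"(step {label!r})"
            )
        steps.append(PathwayStep(label, qualifying))
    return PathwayDefinition("denitrification", tuple(steps))


def classify_pathway(annotation: GenomeAnnotation, pathway: PathwayDefinition) -> PathwayCall:
    """Call a genome complete/partial/absent for one pathway.

    A step is present iff the genome's reaction set intersects the step's
    qualifying set.  Adding reactions can only add steps, so the call is
    monotone under genome growth.
    """
    present = frozenset(
        step.label for step in pathway.steps if annotation.reaction_ids & step.reaction_ids
    )
    if len(present) == len(pathway.steps):
        status = "complete"
    elif present:
        status = "partial"
    else:
        status = "absent"
    return PathwayCall(annotation.genome_id, status, present)


def summarize_group(
    group_id: str, annotations: Iterable[GenomeAnnotation], pathway: PathwayDefinition
) -> DenitrifierSummary:
    calls = [classify_pathway(a, pathway) for a in annotations]
    n = len(calls)
    n_complete = sum(c.status == "complete" for c in calls)
    n_partial = sum(c.status == "partial" for c in calls)
    n_absent = n - n_complete - n_partial
    if n_partial > 0:
        ratio = n_complete / n_partial
    elif n_complete > 0:
        ratio = math.inf
    else:
        ratio = math.nan
    return DenitrifierSummary(
        group_id=group_id,
        n_complete=n_complete,
        n_partial=n_partial,
        n_absent=n_absent,
        prop_complete=n_complete / n if n else 0.0,
        prop_partial=n_partial / n if n else 0.0,
        ratio_complete_to_partial=ratio,
    )


def summarize_denitrifiers(
    communities: Iterable[Community],
    pathway: PathwayDefinition,
    group_by: str = "ecosystem",
) -> list[DenitrifierSummary]:
    """Per-group counts/proportions/ratios, grouping by ecosystem or by study.

    Proportions are fractions of *all* group members (absent genomes included
    in the denominator).
    """
    if group_by not in ("ecosystem", "study"):
        raise ValueError(f"group_by must be 'ecosystem' or 'study' (got {group_by!r})")
    groups: dict[str, list[GenomeAnnotation]] = defaultdict(list)
    for community in communities:
        key = community.ecosystem if group_by == "ecosystem" else community.study_id
        groups[key].extend(community.annotations)
    return [summarize_group(key, groups[key], pathway) for key in sorted(groups)]


# ---------------------------------------------------------------------------
# Pathway TSV I/O: long format (pathway, step, reaction_id); step order is
# order of first appearance.

PATHWAY_COLUMNS = ("pathway", "step", "reaction_id")


def load_pathways(path: str | Path) -> dict[str, PathwayDefinition]:
    path = Path(path)
    with open_text(path) as handle:
        df = pd.read_csv(handle, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in PATHWAY_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s): {missing}")

    step_order: dict[str, list[str]] = defaultdict(list)
    step_rxns: dict[tuple[str, str], set[str]] = defaultdict(set)
    for row in df.itertuples(index=False):
        pw, step, rid = str(row.pathway).strip(), str(row.step).strip(), str(row.reaction_id).strip()
        if not (pw and step and rid):
            continue
        if step not in step_order[pw]:
            step_order[pw].append(step)
        step_rxns[(pw, step)].add(rid)
    return {
        pw: PathwayDefinition(
            pw,
            tuple(PathwayStep(step, frozenset(step_rxns[(pw, step)])) for step in steps),
        )
        for pw, steps in step_order.items()
    }


def save_pathway(pathway: PathwayDefinition, path: str | Path) -> None:
    rows = [
        {"pathway": pathway.name, "step": step.label, "reaction_id": rid}
        for step in pathway.steps
        for rid in sorted(step.reaction_ids)
    ]
    pd.DataFrame(rows, columns=list(PATHWAY_COLUMNS)).to_csv(path, sep="\t", index=False)


DENITRIFIER_SUMMARY_COLUMNS = (
    "group_id", "n_complete", "n_partial", "n_absent",
    "prop_complete", "prop_partial", "ratio_complete_to_partial",
)


def save_denitrifier_summaries(
    summaries: Iterable[DenitrifierSummary], path: str | Path
) -> None:
    rows = [
        {
            "group_id": s.group_id,
            "n_complete": s.n_complete,
            "n_partial": s.n_partial,
            "n_absent": s.n_absent,
            "prop_complete": f"{s.prop_complete:.10g}",
            "prop_partial": f"{s.prop_partial:.10g}",
            "ratio_complete_to_partial": f"{s.ratio_complete_to_partial:.10g}",
        }
        for s in summaries
    ]
    pd.DataFrame(rows, columns=list(DENITRIFIER_SUMMARY_COLUMNS)).to_csv(path, sep="\t", index=False)
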