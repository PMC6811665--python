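"""Reaction-compound universe: the database of biochemical transformations.

A genome's metabolic network is represented as a set of reaction identifiers;
each reaction consumes a set of compounds (its *utilizable reactants*) and
produces another.  Metabolic overlap counts compounds on the consumed side, so
this module is the single place that decides which side of a reaction is
"utilizable": the substrate side for directed reactions, both sides for
reversible ones (a reversible enzyme can consume either side; this is
configurable for sensitivity analyses).

Two on-disk dialects are supported:

* ``native`` — TSV with columns ``reaction_id``, ``substrates``, ``products``,
  ``direction``, ``subsystems``; semicolon-separated in-cell lists; ``#``
  comment lines skipped.
* ``modelseed`` — TSV with columns ``id`` and ``equation``, the equation being
  an arrow-separated compound list in the style of the ModelSEED reactions
  table, e.g. ``(1) cpd00001[0] + (2) cpd00002[0] => (1) cpd00008[0]``.

Stoichiometric coefficients and compartment tags are deliberately discarded:
overlap is presence-based counting over genome-level (uncompartmentalized)
networks.  No currency-compound filter is applied by default; callers may pass
an exclusion set where water/protons/ATP should not count.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Literal

import pandas as pd

from .errors import EquationParseError, TableFormatError, ValidationError

logger = logging.getLogger(__name__)

Direction = Literal["forward", "reverse", "reversible"]
DIRECTIONS: tuple[str, ...] = ("forward", "reverse", "reversible")

NATIVE_COLUMNS = ("reaction_id", "substrates", "products", "direction", "subsystems")
MODELSEED_COLUMNS = ("id", "equation")


def open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open a possibly gzip-compressed text file."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, encoding="utf-8")


@dataclass(frozen=True)
class Compound:
    compound_id: str
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValidationError("compound_id must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """A directed (or reversible) transformation between compound sets."""

    reaction_id: str
    substrates: frozenset[str]
    products: frozenset[str]
    direction: str = "forward"
    subsystems: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.reaction_id:
            raise ValidationError("reaction_id must be non-empty")
        if self.direction not in DIRECTIONS:
            raise ValidationError(
                f"reaction {self.reaction_id!r}: unknown direction {self.direction!r} "
                f"(expected one of {DIRECTIONS})"
            )
        if not self.substrates or not self.products:
            raise ValidationError(
                f"reaction {self.reaction_id!r}: substrates and products must be non-empty"
            )


@dataclass
class ReactionDB:
    """Validated collection of reactions plus the compound table they reference."""

    compounds: dict[str, Compound]
    reactions: dict[str, Reaction]

    def __post_init__(self) -> None:
        for rxn in self.reactions.values():
            missing = (rxn.substrates | rxn.products) - self.compounds.keys()
            if missing:
                raise ValidationError(
                    f"reaction {rxn.reaction_id!r} references unknown compounds: {sorted(missing)}"
                )

    def __len__(self) -> int:
        return len(self.reactions)

    def __contains__(self, reaction_id: str) -> bool:
        return reaction_id in self.reactions

    def __getitem__(self, reaction_id: str) -> Reaction:
        return self.reactions[reaction_id]

    @property
    def subsystems(self) -> set[str]:
        """All subsystem labels carried by at least one reaction."""
        out: set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.subsystems
        return out

    @classmethod
    def from_reactions(cls, reactions: Iterable[Reaction]) -> "ReactionDB":
        """Build a DB, synthesizing the compound table from all referenced ids."""
        rxn_map: dict[str, Reaction] = {}
        compound_ids: set[str] = set()
        for rxn in reactions:
            if rxn.reaction_id in rxn_map:
                raise ValidationError(f"duplicate reaction_id {rxn.reaction_id!r}")
            rxn_map[rxn.reaction_id] = rxn
            compound_ids |= rxn.substrates | rxn.products
        compounds = {cid: Compound(cid) for cid in sorted(compound_ids)}
        return cls(compounds=compounds, reactions=rxn_map)


_ARROW_TOKENS = ("<=>", "=>", "<=")  # longest first: "<=>" contains the others
_COEFF_RE = re.compile(r"^\(\s*[\d.]+\s*\)\s*")
_COMPARTMENT_RE = re.compile(r"\[\w+\]$")


def _parse_side(side: str, equation: str) -> frozenset[str]:
    terms = [t.strip() for t in side.split("+")]
    compounds = set()
    for term in terms:
        if not term:
            raise EquationParseError(f"empty term in equation side: {equation!r}")
        term = _COEFF_RE.sub("", term)
        term = _COMPARTMENT_RE.sub("", term.strip())
        if not term:
            raise EquationParseError(f"term reduced to nothing in {equation!r}")
        compounds.add(term)
    return frozenset(compounds)


def parse_reaction_equation(equation: str) -> tuple[frozenset[str], frozenset[str], str]:
    """Parse a ModelSEED-style equation into (substrates, products, direction).

    ``A => B`` is forward, ``A <=> B`` reversible.  ``C <= A + B`` is stored
    with the consumed side (``A + B``) as substrates and direction ``reverse``,
    i.e. sides are normalized at parse time so downstream code never has to
    re-swap them.
    """
    for arrow in _ARROW_TOKENS:
        if arrow in equation:
            break
    else:
        raise EquationParseError(f"no arrow token (<=>, =>, <=) in equation: {equation!r}")
    left, _, right = equation.partition(arrow)
    if not left.strip() or not right.strip():
        raise EquationParseError(f"empty side in equation: {equation!r}")
    left_set = _parse_side(left, equation)
    right_set = _parse_side(right, equation)
    if arrow == "=>":
        return left_set, right_set, "forward"
    if arrow == "<=>":
        return left_set, right_set, "reversible"
    # "<=": the right-hand side is consumed
    return right_set, left_set, "reverse"


def reactant_set(reaction: Reaction, reversible_both_sides: bool = True) -> frozenset[str]:
    """Compounds this reaction can utilize (consume).

    Directed reactions contribute their substrate side (already normalized at
    parse time for ``<=`` equations).  Reversible reactions contribute both
    sides by default; pass ``reversible_both_sides=False`` to restrict them to
    the substrate side for sensitivity checks.
    """
    if reaction.direction == "reversible" and reversible_both_sides:
        return reaction.substrates | reaction.products
    return reaction.substrates


def _split_cell(cell: str) -> frozenset[str]:
    if not cell or pd.isna(cell):
        return frozenset()
    return frozenset(tok.strip() for tok in str(cell).split(";") if tok.strip())


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s): {missing}")


def load_reaction_db(
    path: str | Path,
    dialect: Literal["native", "modelseed"] = "native",
) -> ReactionDB:
    """Load a reaction database from TSV in the ``native`` or ``modelseed`` dialect.

    Native rows with an unknown direction token or duplicated reaction ids
    raise :class:`ValidationError`.  In the modelseed dialect, rows whose
    equation cannot be parsed are skipped with a logged warning (their count is
    reported), since the upstream table carries untranslatable legacy rows.
    """
    path = Path(path)
    with open_text(path) as handle:
        df = pd.read_csv(handle, sep="\t", comment="#", dtype=str, keep_default_na=False)

    reactions: list[Reaction] = []
    if dialect == "native":
        _require_columns(df, NATIVE_COLUMNS, path)
        for idx, row in df.iterrows():
            direction = row["direction"].strip()
            if direction not in DIRECTIONS:
                raise ValidationError(
                    f"{path} row {idx + 2}: unknown direction token {direction!r}"
                )
            reactions.append(
                Reaction(
                    reaction_id=row["reaction_id"].strip(),
                    substrates=_split_cell(row["substrates"]),
                    products=_split_cell(row["products"]),
                    direction=direction,
                    subsystems=_split_cell(row["subsystems"]),
                )
            )
    elif dialect == "modelseed":
        _require_columns(df, MODELSEED_COLUMNS, path)
        n_skipped = 0
        for idx, row in df.iterrows():
            try:
                substrates, products, direction = parse_reaction_equation(row["equation"])
                reactions.append(
                    Reaction(
                        reaction_id=row["id"].strip(),
                        substrates=substrates,
                        products=products,
                        direction=direction,
                    )
                )
            except (EquationParseError, ValidationError) as exc:
                n_skipped += 1
                logger.warning("%s row %d: skipping unparseable reaction: %s", path, idx + 2, exc)
        if n_skipped:
            logger.warning("%s: skipped %d unparseable reaction row(s)", path, n_skipped)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    db = ReactionDB.from_reactions(reactions)
    logger.info("%s: loaded %d reactions over %d compounds", path, len(db.reactions), len(db.compounds))
    return db


def save_reaction_db(db: ReactionDB, path: str | Path) -> None:
    """Write a database in the native TSV dialect (stable, sorted order)."""
    path = Path(path)
    rows = []
    for rid in sorted(db.reactions):
        rxn = db.reactions[rid]
        rows.append(
            {
                "reaction_id": rid,
                "substrates": ";".join(sorted(rxn.substrates)),
                "products": ";".join(sorted(rxn.products)),
                "direction": rxn.direction,
                "subsystems": ";".join(sorted(rxn.subsystems)),
            }
        )
    pd.DataFrame(rows, columns=list(NATIVE_COLUMNS)).to_csv(path, sep="\t", index=False)


def load_exclusion_list(path: str | Path) -> frozenset[str]:
    """Read a one-compound-per-line exclusion list (currency metabolites etc.)."""
    with open_text(Path(path)) as handle:
        return frozenset(
            line.strip() for line in handle if line.strip() and not line.startswith("#")
        )
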