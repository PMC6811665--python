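"""Full-survey orchestration: filter -> group -> matrices -> summaries -> stats.

A survey run is declared in a single YAML config naming the input tables and
the analysis options; ``run_survey`` executes every stage in method order and
writes one TSV per product plus a run log (package version, seed, counts at
each stage).  Each stage's failure is surfaced with the stage name so a batch
caller can tell which input was at fault.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .annotations import (
    filter_by_completeness,
    group_into_communities,
    load_genome_annotations,
    load_genome_metadata,
    restrict_to_subsystem,
)
from .community_stats import (
    ecosystem_contrast,
    genome_size_anova,
    group_by_ecosystem,
    richness_mo_correlation,
    save_contrasts,
    size_mo_correlation,
)
from .errors import MetabolicOverlapError
from .mo_core import (
    overlap_matrix,
    save_community_summaries,
    save_overlap_matrix,
    summarize_community,
)
from .pathway_completeness import (
    denitrification_pathway,
    load_pathways,
    save_denitrifier_summaries,
    summarize_denitrifiers,
)
from .phylo_association import cophenetic_matrix, mantel_test, pairwise_scatter_correlation

logger = logging.getLogger(__name__)


@dataclass
class SurveyConfig:
    """Declarative description of one survey run."""

    reaction_db: str
    annotations: str
    metadata: str
    outdir: str
    db_dialect: str = "native"
    tree: str | None = None  # newick file, or directory of <study_id>.nwk files
    pathway_tsv: str | None = None
    pathway_name: str | None = None
    run_subsystems: bool = True
    run_denitrifiers: bool = True
    completeness_threshold: float = 50.0
    min_members: int = 2
    statistic: str = "median"
    n_permutations: int = 999
    seed: int = 0
    adjustment: str = "holm"

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness_threshold <= 100.0:
            raise MetabolicOverlapError(
                f"completeness_threshold must lie in [0, 100] (got {self.completeness_threshold})"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "SurveyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


class StageError(MetabolicOverlapError):
    """Wraps a failure with the survey stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except MetabolicOverlapError as exc:
                raise StageError(name, exc) from exc
        return inner
    return wrap


def _load_trees(tree_path: str) -> dict[str, str]:
    """A single newick file maps to key '*', a directory to per-study keys."""
    p = Path(tree_path)
    if p.is_dir():
        return {f.stem: f.read_text().strip() for f in sorted(p.glob("*.nwk"))}
    return {"*": p.read_text().strip()}


def run_survey(config: SurveyConfig) -> dict[str, Any]:
    """Execute the full survey; returns a report dict mirroring what is written.

    Stages: load inputs -> completeness filter -> community grouping ->
    overlap matrices + summaries -> per-subsystem summaries -> denitrifier
    summary -> phylogeny association -> richness/size correlations and
    ecosystem contrasts.  Outputs land in ``config.outdir``.
    """
    from .reaction_db import load_reaction_db

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"version": __version__, "seed": config.seed, "counts": {}}
    log_lines = [f"metabolic-overlap {__version__}", f"seed\t{config.seed}"]

    db = _stage("load-db")(load_reaction_db)(config.reaction_db, dialect=config.db_dialect)
    genomes = _stage("load-annotations")(load_genome_annotations)(config.annotations, db=db)
    metadata = _stage("load-metadata")(load_genome_metadata)(config.metadata)
    report["counts"]["genomes_in"] = len(genomes)

    genomes = _stage("completeness-filter")(filter_by_completeness)(
        genomes, metadata, config.completeness_threshold
    )
    report["counts"]["genomes_after_completeness"] = len(genomes)

    communities = _stage("grouping")(group_into_communities)(
        genomes, metadata, min_members=config.min_members
    )
    report["counts"]["communities"] = len(communities)
    log_lines.append(f"communities\t{len(communities)}")

    matrices = {}
    summaries = []
    matrix_dir = outdir / "matrices"
    matrix_dir.mkdir(exist_ok=True)
    for community in communities:
        matrix = _stage("overlap-matrix")(overlap_matrix)(community, db)
        matrices[community.study_id] = matrix
        save_overlap_matrix(matrix, matrix_dir / f"{community.study_id}.tsv")
        summaries.append(
            _stage("summaries")(summarize_community)(community, db, statistic=config.statistic)
        )
    save_community_summaries(summaries, outdir / "community_summaries.tsv")
    report["summaries"] = summaries

    if config.run_subsystems:
        subsystem_rows = []
        for category in sorted(db.subsystems):
            for community in communities:
                restricted = community.__class__(
                    study_id=community.study_id,
                    ecosystem=community.ecosystem,
                    members=tuple(
                        m.__class__(restrict_to_subsystem(m.annotation, db, category), m.metadata)
                        for m in community.members
                    ),
                )
                s = _stage("subsystem-mo")(summarize_community)(
                    restricted, db, statistic=config.statistic
                )
                subsystem_rows.append(
                    {
                        "subsystem": category,
                        "study_id": s.study_id,
                        "ecosystem": s.ecosystem,
                        "mo_central": f"{s.mo_central:.10g}",
                        "normalized_mo": f"{s.normalized_mo:.10g}",
                    }
                )
        import pandas as pd

        pd.DataFrame(subsystem_rows).to_csv(outdir / "subsystem_mo.tsv", sep="\t", index=False)
        report["counts"]["subsystem_rows"] = len(subsystem_rows)

    if config.run_denitrifiers:
        if config.pathway_tsv:
            pathways = _stage("pathway-load")(load_pathways)(config.pathway_tsv)
            name = config.pathway_name or next(iter(pathways))
            pathway = pathways[name]
        else:
            pathway = _stage("pathway-default")(denitrification_pathway)(db)
        denit = _stage("denitrifiers")(summarize_denitrifiers)(communities, pathway)
        save_denitrifier_summaries(denit, outdir / "denitrifier_summary.tsv")
        report["denitrifiers"] = denit

    if config.tree:
        trees = _stage("tree-load")(_load_trees)(config.tree)
        assoc_rows = []
        for community in communities:
            newick = trees.get(community.study_id, trees.get("*"))
            if newick is None:
                logger.warning("no tree for study %s; skipped", community.study_id)
                continue
            ids = [g for g in community.genome_ids]
            dmat = _stage("cophenetic")(cophenetic_matrix)(newick, tip_subset=ids)
            if len(dmat) < 3:
                logger.warning(
                    "study %s: only %d genome(s) in tree; association skipped",
                    community.study_id, len(dmat),
                )
                continue
            keep = [i for i, g in enumerate(community.genome_ids) if g in dmat.genome_ids]
            if len(keep) < len(community.genome_ids):
                logger.warning(
                    "study %s: %d genome(s) absent from tree, dropped pairwise",
                    community.study_id, len(community.genome_ids) - len(keep),
                )
            matrix = matrices[community.study_id]
            sub = matrix.__class__(
                tuple(matrix.genome_ids[i] for i in keep),
                matrix.values[np.ix_(keep, keep)],
            )
            mantel = _stage("mantel")(mantel_test)(
                dmat, sub, n_perm=config.n_permutations, seed=config.seed
            )
            scatter = _stage("scatter-corr")(pairwise_scatter_correlation)(dmat, sub)
            assoc_rows.append(
                {
                    "study_id": community.study_id,
                    "ecosystem": community.ecosystem,
                    "n_genomes": len(dmat),
                    "mantel_r": f"{mantel.r:.10g}",
                    "mantel_p": f"{mantel.p_value:.10g}",
                    "n_permutations": mantel.n_permutations,
                    "spearman_r": f"{scatter.r:.10g}",
                    "spearman_p": f"{scatter.p_value:.10g}",
                }
            )
        import pandas as pd

        pd.DataFrame(assoc_rows).to_csv(outdir / "phylo_association.tsv", sep="\t", index=False)
        report["phylo_association"] = assoc_rows

    # survey-wide statistics battery
    stats_lines = []
    if len(summaries) >= 3:
        rich = _stage("richness-correlation")(richness_mo_correlation)(summaries)
        size = _stage("size-correlation")(size_mo_correlation)(summaries)
        report["richness_mo"] = rich
        report["size_mo"] = size
        stats_lines.append(f"richness_mo_kendall_tau\t{rich.r:.10g}\tp\t{rich.p_value:.10g}")
        stats_lines.append(f"size_mo_spearman_r\t{size.r:.10g}\tp\t{size.p_value:.10g}")

    grouped = group_by_ecosystem(summaries)
    eligible = {k: v for k, v in grouped.items() if len(v) >= 2}
    if len(eligible) >= 2:
        omnibus, contrasts = _stage("contrasts")(ecosystem_contrast)(
            eligible, adjust=config.adjustment
        )
        save_contrasts(contrasts, outdir / "ecosystem_contrasts.tsv")
        report["omnibus"] = omnibus
        report["contrasts"] = contrasts
        stats_lines.append(
            f"kruskal_wallis_H\t{omnibus.statistic:.10g}\tdf\t{omnibus.df:g}"
            f"\tp\t{omnibus.p_value:.10g}"
        )
        sizes = {
            k: [s.median_genome_size_bp for s in v] for k, v in eligible.items()
        }
        anova = _stage("anova")(genome_size_anova)(sizes)
        report["size_anova"] = anova
        stats_lines.append(
            f"genome_size_anova_F\t{anova.statistic:.10g}\tp\t{anova.p_value:.10g}"
        )

    (outdir / "omnibus_statistics.txt").write_text("\n".join(stats_lines) + "\n")
    log_lines += [f"{k}\t{v}" for k, v in report["counts"].items()]
    log_lines.append("---- machine-parsable summary ----")
    log_lines += stats_lines
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    logger.info("survey complete: %s", outdir)
    return report
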