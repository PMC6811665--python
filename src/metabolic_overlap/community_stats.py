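"""Survey-level statistics: richness, genome size and ecosystem contrasts.

Once every study has a community summary, the survey asks three questions:

* does community richness (number of genomes per study) predict the central
  overlap? — rank correlation (Kendall tau by default);
* does genome size predict overlap? — rank correlation on sizes vs MO;
* does normalized overlap differ between ecosystems? — Kruskal-Wallis omnibus
  (chi-square approximated, tie-corrected) followed by Dunn's z post-hoc
  contrasts with multiplicity adjustment, plus a plain one-way ANOVA for
  genome sizes.

Kruskal-Wallis and the one-way ANOVA come from scipy; Dunn's test is coded
here (rank-mean z statistics with the pooled tie correction); multiplicity
adjustment (Holm by default, Benjamini-Hochberg optional) is delegated to
statsmodels.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .mo_core import CommunitySummary
from .phylo_association import AssociationResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OmnibusResult:
    """A k-group omnibus test (Kruskal-Wallis H or one-way ANOVA F)."""

    statistic_name: str
    statistic: float
    df: float
    p_value: float


@dataclass(frozen=True)
class ContrastRow:
    group_a: str
    group_b: str
    statistic: float  # Dunn z
    p_raw: float
    p_adjusted: float


def group_by_ecosystem(
    summaries: Iterable[CommunitySummary],
) -> dict[str, list[CommunitySummary]]:
    """Partition summaries by ecosystem label (each summary in exactly one group)."""
    grouped: dict[str, list[CommunitySummary]] = {}
    for s in summaries:
        grouped.setdefault(s.ecosystem, []).append(s)
    return grouped


def _rank_correlation(
    xs: np.ndarray, ys: np.ndarray, method: str
) -> AssociationResult:
    if len(xs) < 3:
        raise ValidationError(f"correlation needs >= 3 observations (got {len(xs)})")
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return AssociationResult(method, math.nan, math.nan, 0, None, len(xs), True)
    if method == "kendall":
        res = stats.kendalltau(xs, ys)
    elif method == "spearman":
        res = stats.spearmanr(xs, ys)
    elif method == "pearson":
        res = stats.pearsonr(xs, ys)
    else:
        raise ValueError(f"unknown method {method!r}")
    return AssociationResult(method, float(res.statistic), float(res.pvalue), 0, None, len(xs))


def richness_mo_correlation(
    summaries: Sequence[CommunitySummary], method: str = "kendall"
) -> AssociationResult:
    """Rank correlation between community richness (n genomes) and central MO."""
    xs = np.array([s.n_genomes for s in summaries], dtype=float)
    ys = np.array([s.mo_central for s in summaries], dtype=float)
    return _rank_correlation(xs, ys, method)


def size_mo_correlation(
    records: Sequence[CommunitySummary] | Sequence[tuple[float, float]],
    method: str = "spearman",
) -> AssociationResult:
    """Rank correlation between genome size and MO.

    Accepts either community summaries (median genome size vs central MO) or
    genome-level ``(genome_size_bp, mo)`` pairs.
    """
    if records and isinstance(records[0], CommunitySummary):
        xs = np.array([s.median_genome_size_bp for s in records], dtype=float)
        ys = np.array([s.mo_central for s in records], dtype=float)
    else:
        arr = np.asarray(records, dtype=float)
        xs, ys = arr[:, 0], arr[:, 1]
    return _rank_correlation(xs, ys, method)


_ADJUST_METHODS = {"holm": "holm", "benjamini-hochberg": "fdr_bh", "bh": "fdr_bh", "fdr_bh": "fdr_bh"}


def _adjust_pvalues(p_raw: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return p_raw.copy()
    if method not in _ADJUST_METHODS:
        raise ValueError(f"unknown adjustment {method!r}")
    return multipletests(p_raw, method=_ADJUST_METHODS[method])[1]


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]], adjust: str = "holm"
) -> list[ContrastRow]:
    """Dunn's z test on all unordered group pairs after a Kruskal-Wallis omnibus.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T = sum(t^3 - t) over tied value groups in the pooled ranking;
    two-sided normal p, adjusted by Holm (default), Benjamini-Hochberg or none.
    """
    labels = sorted(groups)
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in labels])
    sizes = {g: len(groups[g]) for g in labels}
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)

    mean_ranks = {}
    start = 0
    for g in labels:
        mean_ranks[g] = ranks[start:start + sizes[g]].mean()
        start += sizes[g]

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    pairs = list(itertools.combinations(labels, 2))
    zs, ps = [], []
    for a, b in pairs:
        se = math.sqrt(variance_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else math.nan
        zs.append(z)
        ps.append(2.0 * stats.norm.sf(abs(z)) if not math.isnan(z) else math.nan)
    p_adj = _adjust_pvalues(np.asarray(ps), adjust)
    return [
        ContrastRow(a, b, zs[i], ps[i], float(p_adj[i]))
        for i, (a, b) in enumerate(pairs)
    ]


def ecosystem_contrast(
    grouped: Mapping[str, Sequence[CommunitySummary]],
    response: str = "normalized_mo",
    adjust: str = "holm",
) -> tuple[OmnibusResult, list[ContrastRow]]:
    """Kruskal-Wallis omnibus + Dunn post-hoc on a community summary field.

    ``response`` names any numeric :class:`CommunitySummary` field
    (``normalized_mo``, ``mo_central``, ``n_genomes``, ...).
    """
    if len(grouped) < 2:
        raise ValidationError("ecosystem contrast needs >= 2 groups")
    values: dict[str, list[float]] = {}
    for label, summaries in grouped.items():
        if len(summaries) < 2:
            raise ValidationError(f"group {label!r} needs >= 2 communities")
        values[label] = [float(getattr(s, response)) for s in summaries]

    samples = [values[g] for g in sorted(values)]
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):  # scipy.kruskal raises on all-identical data
        omnibus = OmnibusResult("kruskal-wallis", 0.0, len(samples) - 1, 1.0)
    else:
        h, p = stats.kruskal(*samples)
        omnibus = OmnibusResult("kruskal-wallis", float(h), len(samples) - 1, float(p))
    contrasts = dunn_posthoc(values, adjust=adjust)
    return omnibus, contrasts


def genome_size_anova(grouped_sizes: Mapping[str, Sequence[float]]) -> OmnibusResult:
    """One-way Gaussian-theory ANOVA on genome sizes across ecosystems."""
    if len(grouped_sizes) < 2:
        raise ValidationError("ANOVA needs >= 2 groups")
    samples = [np.asarray(grouped_sizes[g], dtype=float) for g in sorted(grouped_sizes)]
    f, p = stats.f_oneway(*samples)
    return OmnibusResult("anova", float(f), len(samples) - 1, float(p))


CONTRAST_COLUMNS = ("group_a", "group_b", "statistic", "p_raw", "p_adjusted")


def save_contrasts(contrasts: Iterable[ContrastRow], path: str | Path) -> None:
    rows = [
        {
            "group_a": c.group_a,
            "group_b": c.group_b,
            "statistic": f"{c.statistic:.10g}",
            "p_raw": f"{c.p_raw:.10g}",
            "p_adjusted": f"{c.p_adjusted:.10g}",
        }
        for c in contrasts
    ]
    pd.DataFrame(rows, columns=list(CONTRAST_COLUMNS)).to_csv(path, sep="\t", index=False)
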