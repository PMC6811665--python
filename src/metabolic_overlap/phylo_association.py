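"""Phylogenetic distance vs metabolic overlap: cophenetic matrices and Mantel tests.

Closely related genomes tend to share pathways, so overlap should decay with
phylogenetic (cophenetic/patristic) distance.  Two complementary tests are
provided:

* a Mantel permutation test between the phylogenetic distance matrix and the
  overlap matrix of a community (rows and columns of one matrix are permuted
  together to build the null), and
* the plain rank correlation over all genome pairs pooled into a scatter,
  with the standard large-sample p-value.

The Mantel permutation machinery is implemented here because the exact
conventions matter for reproducibility: two-sided p = (#{|r_perm| >= |r_obs|}
+ 1) / (n_perm + 1), Spearman achieved by rank-transforming the condensed
triangles once (label permutation only permutes condensed entries, so ranks
need not be recomputed), and an explicit integer seed recorded in the result.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
from scipy import stats
from scipy.spatial.distance import squareform

from .errors import TreeError, ValidationError
from .mo_core import OverlapMatrix

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative genome x genome distance matrix, zero diagonal."""

    genome_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genome_ids)
        if self.values.shape != (n, n):
            raise ValidationError(f"matrix shape {self.values.shape} does not match {n} ids")
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("distance matrix must be symmetric")
        if (self.values < 0).any():
            raise ValidationError("distances must be non-negative")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValidationError("distance matrix must have a zero diagonal")

    def __len__(self) -> int:
        return len(self.genome_ids)


@dataclass(frozen=True)
class AssociationResult:
    """A correlation estimate with its provenance.

    ``n_permutations`` is 0 for non-permutation tests; ``degenerate`` flags a
    constant input vector, in which case ``r`` and ``p_value`` are NaN.
    """

    statistic_name: str  # spearman | kendall | pearson
    r: float
    p_value: float
    n_permutations: int = 0
    seed: int | None = None
    n_obs: int = 0
    degenerate: bool = False


def cophenetic_matrix(
    newick: str, tip_subset: Sequence[str] | None = None
) -> DistanceMatrix:
    """Patristic distances (sum of branch lengths along tree paths) between tips.

    ``newick`` may be a newick string or a path readable by dendropy.  Tips in
    ``tip_subset`` missing from the tree are dropped with a warning; the
    matrix is ordered by subset order (or tree taxon order when no subset is
    given).  Trees without branch lengths are rejected.
    """
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"malformed newick: {exc}") from exc

    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise TreeError("tree lacks branch lengths on at least one edge")

    labels = [t.label for t in tree.taxon_namespace]
    if tip_subset is not None:
        present = [t for t in tip_subset if t in labels]
        missing = [t for t in tip_subset if t not in labels]
        if missing:
            logger.warning("%d tip(s) not in tree, dropped: %s", len(missing), missing[:10])
        labels = present

    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            values[i, j] = d
            values[j, i] = d
    return DistanceMatrix(tuple(labels), values)


def _align_condensed(
    d_phylo: DistanceMatrix | OverlapMatrix | np.ndarray,
    d_mo: DistanceMatrix | OverlapMatrix | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Align two matrices on ids and return their condensed strict lower triangles."""
    a_ids = getattr(d_phylo, "genome_ids", None)
    b_ids = getattr(d_mo, "genome_ids", None)
    a = np.asarray(getattr(d_phylo, "values", d_phylo), dtype=float)
    b = np.asarray(getattr(d_mo, "values", d_mo), dtype=float)

    if a_ids is not None and b_ids is not None:
        sym_diff = set(a_ids) ^ set(b_ids)
        if sym_diff:
            raise ValidationError(
                f"matrices cover different genomes; symmetric difference: {sorted(sym_diff)}"
            )
        if a_ids != b_ids:  # same set, different order: align the second matrix
            order = [b_ids.index(g) for g in a_ids]
            b = b[np.ix_(order, order)]
    if a.shape != b.shape:
        raise ValidationError(f"matrix shapes differ: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise ValidationError(f"association tests need >= 3 genomes (got {n})")
    iu = np.tril_indices(n, k=-1)
    return a[iu], b[iu], n


def mantel_test(
    d_phylo: DistanceMatrix | OverlapMatrix | np.ndarray,
    d_mo: DistanceMatrix | OverlapMatrix | np.ndarray,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int | None = None,
) -> AssociationResult:
    """Mantel permutation test between two square symmetric matrices.

    r is the Pearson (or Spearman, via rank transform) correlation of the
    vectorized strict lower triangles; the null is built by permuting rows and
    columns of the second matrix simultaneously ``n_perm`` times; the
    two-sided p-value is (#{|r_perm| >= |r_obs|} + 1) / (n_perm + 1).
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"method must be 'spearman' or 'pearson' (got {method!r})")
    vec_a, vec_b, n = _align_condensed(d_phylo, d_mo)
    if method == "spearman":
        vec_a = stats.rankdata(vec_a)
        vec_b = stats.rankdata(vec_b)
    n_pairs = len(vec_a)

    sd_a, sd_b = vec_a.std(), vec_b.std()
    if sd_a == 0 or sd_b == 0:
        return AssociationResult(method, math.nan, math.nan, n_perm, seed, n_pairs, True)

    z_a = (vec_a - vec_a.mean()) / sd_a
    z_b = (vec_b - vec_b.mean()) / sd_b
    r_obs = float(np.mean(z_a * z_b))

    # permutations act on labels, so permute the square form of the (already
    # rank-transformed) second matrix and re-extract the triangle; the
    # condensed mean/sd are invariant under label permutation.
    square_b = squareform(z_b, checks=False)
    iu = np.tril_indices(n, k=-1)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        order = rng.permutation(n)
        zb_perm = square_b[np.ix_(order, order)][iu]
        r_perm = float(np.mean(z_a * zb_perm))
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return AssociationResult(method, r_obs, p, n_perm, seed, n_pairs)


def pairwise_scatter_correlation(
    d_phylo: DistanceMatrix | OverlapMatrix | np.ndarray,
    d_mo: DistanceMatrix | OverlapMatrix | np.ndarray,
    method: str = "spearman",
) -> AssociationResult:
    """Plain rank correlation over pooled genome pairs (no permutation null).

    This is the scatter-plot statistic: each observation is one genome pair's
    (phylogenetic distance, MO) tuple from the strict lower triangles.
    """
    if method not in ("spearman", "kendall"):
        raise ValueError(f"method must be 'spearman' or 'kendall' (got {method!r})")
    vec_a, vec_b, _ = _align_condensed(d_phylo, d_mo)
    if np.all(vec_a == vec_a[0]) or np.all(vec_b == vec_b[0]):
        return AssociationResult(method, math.nan, math.nan, 0, None, len(vec_a), True)
    if method == "spearman":
        res = stats.spearmanr(vec_a, vec_b)
    else:
        res = stats.kendalltau(vec_a, vec_b)
    return AssociationResult(method, float(res.statistic), float(res.pvalue), 0, None, len(vec_a))
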