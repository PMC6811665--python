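# Methods

## The metric

Metabolic overlap (MO) quantifies how much of two organisms' substrate space
is shared, at the genome scale. Each genome is reduced to the set of reactions
its annotation supports; each reaction contributes its *utilizable reactants*
— the compounds on its consumed side. The genome's **reactant profile** is the
union of those compounds over all its reactions, and for genomes *i*, *j*

    MO(i, j) = | P_i ∩ P_j |

where `P_g` is the reactant profile of genome *g*. Counting shared reactants
rather than shared reactions deliberately credits convergent routes: two
organisms that degrade the same substrate through different enzymes still
overlap. Because the count is presence-based, stoichiometric coefficients and
compartment tags are stripped at parse time.

Decisions the definition leaves open, and how this package resolves them:

* **Reversible reactions** contribute both sides to the profile (a reversible
  enzyme can consume either side). `reactant_set(..., reversible_both_sides=False)`
  restricts to the substrate side for sensitivity checks.
* **Currency compounds** (water, protons, ATP, ...) are *not* excluded by
  default; an explicit exclusion set can be passed to `reactant_profile`
  (or given to the loaders as a one-per-line file). Excluding them lowers
  every pairwise count by roughly the same amount, so rankings are robust,
  but the default keeps the raw definition.
* **Directionality** of `<=`-style equations is normalized at parse time: the
  consumed side is always stored as `substrates`, so downstream code never
  re-interprets arrows.

## Community summaries

For a community (all genomes recovered in one study; studies with a single
genome are excluded since they admit no pair), the overlap structure is a
symmetric genome × genome integer matrix with each genome's own profile size
on the diagonal. The community-level MO is the **median** (default; mean
available) of the n(n−1)/2 unique off-diagonal entries. Because organisms
with larger genomes encode more reactions and therefore overlap more, the
cross-ecosystem comparison uses the **genome-size-normalized MO**:

    normalized_mo = mo_central / median(genome_size_bp)       [compounds/bp]

with the median genome size of the community's members as the divisor.
Typical values land in the 1e-6 .. 1e-4 compounds/bp range.

Subsystem-restricted MO intersects every genome's reaction set with the
reactions carrying one subsystem label (e.g. Nitrogen) before profiling; it
is always ≤ the unrestricted MO for the same pair. The shipped category list
has 13 metabolism subsystems (Amino Acid … Sulfur); databases may carry any
labels, and a reaction→subsystem TSV can override them.

## Denitrification completeness

Denitrification is modelled as four reduction steps (NO3⁻→NO2⁻→NO→N2O→N2).
A step is present in a genome iff its reaction set intersects the step's
qualifying reactions; genomes are **complete** (all four steps), **partial**
(a proper non-empty subset) or **absent**. The default definition binds each
step to whichever reactions in the loaded database convert the step's
substrate/product pair (either orientation for reversible reactions); any
pathway can be supplied as a (pathway, step, reaction_id) TSV since reaction
id schemes differ between databases. Group summaries report counts,
proportions of the whole community (absent genomes stay in the denominator),
and the complete:partial ratio — infinite when there are complete but no
partial denitrifiers, NaN (flagged) when there are neither.

## Phylogeny association

Cophenetic (patristic) distances are extracted from newick trees with
dendropy; trees must carry branch lengths. Two association tests are run
side by side:

* **Mantel permutation test** between the distance matrix and the overlap
  matrix: r is the correlation (Spearman by default, via a one-time rank
  transform of the condensed triangles) of the vectorized strict lower
  triangles; the null permutes rows and columns of one matrix together;
  two-sided p = (#{|r_perm| ≥ |r_obs|} + 1) / (n_perm + 1), default 999
  permutations, seeded and bit-reproducible.
* **Scatter rank correlation** over pooled genome pairs with the standard
  large-sample p-value — the statistic a per-ecosystem scatter plot reports.

Degenerate inputs (a constant triangle) yield a flagged NaN result rather
than an exception. Genomes missing from the tree are dropped pairwise with a
logged count.

## Survey statistics

Across communities: Kendall τ between richness (genomes per study) and
central MO; Spearman between genome size and MO; Kruskal–Wallis
(tie-corrected, χ²-approximated) on normalized MO between ecosystems with
Dunn's z post-hoc (Holm adjustment by default, Benjamini–Hochberg or none by
flag — tie variance term `Σ(t³−t)/(12(N−1))` included); and a plain one-way
ANOVA on genome sizes. scipy supplies the omnibus tests and correlations;
statsmodels the multiplicity adjustment; Dunn's z is implemented here.

## The synthetic generator

Real inputs require external genome downloads and annotation services, so the
generator emulates the statistical structure the analysis assumes:

* **Reaction universe** — `n_reactions` = 400 reactions over `n_compounds` =
  300 compounds, 1–3 substrates and products each sampled without
  replacement, ~20% reversible, subsystem labels round-robin over the 13
  categories.
* **Tree** — sequential random pairwise joins with exponential branch
  lengths, mean 0.1 per branch. With 30 tips that yields root-to-tip depths
  near 0.5, so at the default rates a typical lineage retains most of its
  repertoire while pairs diverge measurably.
* **Gain/loss process** — per-reaction, per-branch Bernoulli: a present
  reaction is lost with probability 1−exp(−loss·L), an absent one gained
  with 1−exp(−gain·L); defaults gain 0.05, loss 0.3, root repertoire 150.
  This is the simplest process producing the distance-decay of overlap the
  association tests detect. Note the regime structure: as rate·L→∞ the flip
  probability →1 and a child becomes the deterministic complement of its
  parent, so "independent tips" are approached when the per-branch flip
  probability is near ½ (rate·L ≈ ln 2), not at extreme rates.
* **Genome sizes** — bp_per_reaction = 10 kbp per encoded reaction plus
  Gaussian noise (sd 100 kbp), floored at 1 bp; this plants the strong
  positive size–MO coupling. Completeness is uniform on [50, 100)%, the
  range reported for real MAG collections.
* **Denitrifier planting** — fractions (default 0.3 complete / 0.2 partial)
  are apportioned by largest remainder, so small communities hit the
  requested counts exactly; non-pathway reactions are untouched.
* **Multi-study surveys** — studies share one database (with the four
  canonical denitrification reactions added so the pathway is expressible)
  but evolve on independent trees with 6–24 tips; the root repertoire
  shrinks ~6 reactions per extra tip, planting the negative richness–MO
  dependence the survey statistics should recover.

Everything is driven by `numpy.random.default_rng` seeds; a bundle written
twice with one seed is byte-identical (manifest paths are stored relative to
the bundle directory for this reason).

What the generator does **not** emulate: mass balance and realistic network
topology, biased taxon sampling, annotation error structure (missing or
spurious reactions correlated with completeness), horizontal transfer, and
abundance information. Passing tests therefore demonstrate the correctness
and statistical calibration of the machinery, not ecological conclusions
about real communities.

## Numerical and design notes

* Overlap matrices are dense `int64`; communities here are at most hundreds
  of genomes, so sparse storage would buy nothing.
* Median vs mean: the community central statistic and the size divisor both
  default to the median (robust to a single large generalist or genome);
  the mean is exposed everywhere for comparison.
* The Mantel permutation comparison uses a 1e-12 tolerance on |r_perm| ≥
  |r_obs| to make tie handling float-robust; the +1-corrected p can never be
  exactly zero.
* Completeness filtering is inclusive (≥ threshold) and defaults to 50%,
  the floor of the range real MAG metadata reports.
* Validation is strict on structure (duplicate reaction ids, unknown
  direction tokens, out-of-range completeness are errors) but lenient by
  default on annotation rows citing unknown reaction ids (warn and keep),
  because MAG annotations routinely cite deprecated ids; `strict=True`
  flips this.
* Test problem sizes (e.g. 100 random communities up to 50×200 for oracle
  equivalence, 50 replicates for planted-signal recovery, 200/500 replicates
  for null calibration) were chosen to make the checks statistically
  meaningful while keeping the whole suite fast to iterate on.

## Known limitations

* MO is annotation-quality bound: unannotated genes simply vanish from the
  profile, and the metric inherits any database bias.
* No gene-copy, transcript or abundance weighting; a pathway encoded once
  counts as much as one encoded in ten paralogs.
* The Mantel test here has no partial/covariate form, so genome size (which
  correlates with both overlap and phylogenetic breadth) is not controlled
  for in the association.
* The default denitrification step→reaction binding matches compound pairs
  only; databases whose nitrogen intermediates use different identifiers
  need an explicit pathway TSV.
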