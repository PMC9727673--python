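# Methods

`phyloprior` implements a phylogeny-based spatial conservation
prioritization analysis: from binary species ranges on an equal-area grid
and a dated phylogeny it builds branch-occurrence features, ranks cells by
iterative marginal loss (the Zonation family of algorithms), and audits how
well an existing and an expanded protected-area (PA) network represent the
tree of life. Because the package ships no real data, a first-class
synthetic-landscape generator supplies inputs with the statistical
structure the analysis assumes; every stage is deterministic given a single
top-level seed.

## The prioritization model

Let `a[j,i] ∈ {0,1}` indicate feature `j` (a phylogenetic branch) in cell
`i`, with weight `w[j]` equal to the branch length and per-cell cost
`c[i]` (1 by default). With `q[j,i] = a[j,i] / n_j` where `n_j` is the
number of *remaining* cells occupied by `j`, the marginal loss of removing
cell `i` is

* CAZ (core-area zonation): `max_j w[j] q[j,i] / c[i]`
* ABF (additive benefit function): `Σ_j w[j] q[j,i] / c[i]`

The landscape is eroded one cell at a time, always removing a cell with
minimal loss and updating the `n_j` before the next step; exact ties are
broken by a seeded random draw. No batched ("warp") removal is used: at
desk scale exact greedy is affordable and is the cleanest behaviour to
verify against an independent oracle, which the test suite does exhaustively
on small instances. ABF is the plain weighted sum (an optional benefit
exponent is deliberately not applied). The priority of a cell is
`removal_order / n_cells`, so the top fraction `f` of the landscape is the
`⌈f·n⌉` cells removed last. Cells locked in by the PA mask are removed only
after every free cell, which pins existing PAs to the top of the ranking;
expansion areas are then the best-ranked free cells.

CAZ is the headline rule: protecting the single longest branch in a cell is
the largest possible gain for the tree of life, and on synthetic landscapes
the two rules' priority maps correlate strongly (the acceptance script
recomputes this correlation each run, typically r ≈ 0.8).

## Branch features and Faith's PD

A branch (the edge above a node; the root edge is excluded) occupies the
union of its descendant tips' cells, so ancestor branches always occupy
supersets of their descendants' cells. Faith's PD of a cell is the summed
length of branches present in it, which equals the length of the subtree
connecting the cell's species to the root; the path to the root is included,
so a single-species cell has nonzero PD. Branch identifiers are content
hashes of the descendant tip set, stable across runs and topology-neutral
file orderings.

Species-level trees are built by grafting species into a genus-level
backbone: each genus tip is replaced by a randomly resolved birth–death
subtree whose crown age is drawn uniformly from 50–90% of the genus stem
length, preserving ultrametricity. Terminal branches of simulated
birth–death trees are padded by a small constant (1–5% of depth) because
the stopping rule otherwise leaves the youngest cherry with zero-length
branches; all downstream code requires strictly positive lengths.

## Suitability modelling chain

The emphasis is on the post-processing contract, not the classifier: the
suitability model is a single L2-regularized logistic scorer
(scikit-learn) on the climate predictors. Per species: pseudo-absences are
sampled uniformly from unoccupied cells at a 1:1 ratio (configurable; the
choice is a convention, nothing downstream depends on it strongly);
ten stratified 80/20 train/test splits are drawn; each replicate is scored
on its held-out cells by the true skill statistic
(TSS = sensitivity + specificity − 1) at the replicate's max-TSS threshold;
replicates with TSS ≥ 0.5 are retained and their suitability maps
median-ensembled (cell-wise; even counts average the middle pair). The
ensemble is binarized at its max-TSS threshold (candidates are all observed
scores plus the 0/1 endpoints, smallest maximizer wins ties, comparison is
`score ≥ threshold`), clipped to the 200 km-buffered minimum convex polygon
of the occurrences (planar Euclidean distances on the equal-area grid;
one or two occurrences degrade to a buffered point/segment), and projected
to the future climate under three dispersal scenarios: full (unconstrained),
none (future ∩ current), and limited (future ∩ cells within 200 km of the
current range, i.e. 20 km per decade over a century). The buffer clip is
applied after ensembling, to the ensembled binary map. Species with no
retained replicate are flagged unmodellable and excluded with a log entry.

## Assessment rules

* A cell is protected when PA polygons cover **strictly more than 30%** of
  its area.
* Representation targets scale with range area `A` (km²): 100% below
  1 000 km², 10% above 250 000 km², log-linear in between
  (`target = 1 − 0.9·(log A − log 10³)/(log 2.5·10⁵ − log 10³)`). The same
  rule applies to species and branches; all three anchors are config keys.
* Gap classes from achieved/target: `unprotected` (no protected cell),
  `gap` (≤ 0.2), `partial_gap` (0.2–0.9, right-inclusive), `covered`
  (> 0.9).
* Habitat-change vulnerability: `csh = (future − current)/current`;
  `lost` when the future range is empty, `greatly_expanded` when
  csh > 0.8, `contracted` when negative, otherwise `stable`; a unit with no
  current range has undefined csh and is flagged.
* PD quintiles are rank-based with ties assigned to the lower class; human
  pressure classes are low (< 0.1), moderate ([0.1, 0.4)), high (≥ 0.4).
* Novel climate (area of applicability): variables standardized by the
  reference mean/sd; a projected cell's dissimilarity is its
  nearest-neighbour distance to the reference cells scaled by the mean
  pairwise reference distance; cells above the 0.95 quantile of the
  reference's own leave-one-out dissimilarities are flagged. When the
  projection equals the reference nothing is flagged (all distances are 0);
  on exchangeable data the flag rate calibrates to ≈ 1 − quantile, which
  the tests verify with independent white-noise fields.
* Group pressure contrasts (existing PA / expansion / non-PA) are
  descriptive summaries (mean, sd, n, class shares); formal ANOVA-style
  inference is out of scope and replaced by seeded simulation sign-checks.

## Synthetic landscape generator

The generator emulates, with no real-world data, the features the analysis
relies on — and only those:

* **Grid**: 30 × 30 cells of 20 × 20 km (400 km²). Small enough for the
  exact greedy ranking to run in seconds, large enough for ~200–300 branch
  features.
* **Climate**: per variable, Gaussian-smoothed white noise re-standardized
  to zero mean/unit variance; kernel sigma is `(corr_len − 1)/2` so
  `corr_len = 1` is spatially independent. Six variables named after the
  bioclimatic set commonly used for woody plants. The future scenario adds
  a constant per-variable shift plus small cell noise; the default shift
  (0.4, 0.3, 0.3, 0.1, 0.0, −0.1 sd) is warming-dominated and yields a
  novel-climate share of roughly 15–25% — substantial but minority, as in
  realistic end-of-century projections.
* **Tree**: birth–death (birth 1.0, death 0.2 per lineage per unit time)
  conditioned on the tip count.
* **Ranges**: niche optima evolve on the tree by Brownian motion
  (sd 0.5 per unit time per climate axis); a species occupies cells where a
  dimension-normalized Gaussian suitability (breadth 0.7 sd) is ≥ 0.55.
  These three constants were chosen together so that, at the default grid,
  the range-size distribution is right-skewed (median ≈ 5% of the
  landscape, a few widespread species), sister species have visibly
  correlated ranges, and most species clear the 20-occurrence floor.
  Species below the floor have their tip optimum redrawn from the parent
  node up to 10 times, then are dropped with a logged count, so the floor
  cannot silently prune whole clades.
* **Protection and pressure**: the human modification index is a rank
  transform (squared, giving the right-skew of real pressure maps) of a
  blend of the first climate variable (a warm/lowland proxy) and smooth
  noise. PA cover goes to the top `pa_fraction` cells of a smooth score
  field penalized by `2·pa_bias` standardized HMI units; selected cells get
  cover in (0.5, 1], so the realized share of protected cells at the 30%
  cutoff equals the target up to rounding. At `pa_bias = 1` protection sits
  firmly in the least-modified (cold, remote) landscapes — the historical
  placement pattern whose consequences the analysis measures.

What the generator does **not** emulate: real geography and floristics,
range cohesion beyond what climate autocorrelation induces, land-cover
dynamics, observation error in occurrences, and spatial bias in sampling.
Passing tests therefore demonstrate the correctness of the algorithms and
the direction of the headline effects (biased PAs under-represent the tree
of life; prioritized expansion outperforms random expansion; branch-weighted
prioritization is at least as good as species-based when ranges carry
phylogenetic signal), not the magnitudes that a real atlas would produce.

## Numerical and design choices

* Cell-level joins use `cell_id` only; CSV is the canonical format for all
  layers (exact, diffable); Newick for trees. No raster export.
* Distances are planar Euclidean in km — the grid is already equal-area.
* One top-level seed drives every stochastic element (field noise, tree,
  niche walk, PA placement, pseudo-absences, splits, tie-breaks) through
  deterministically derived per-stage seeds; reruns are bit-identical.
* The tie rule in the prioritizer consumes randomness only when two or more
  cells attain exactly the minimal loss, which keeps the removal order
  comparable with reference implementations.
* The polytomy-resolution rates default to the synthetic tree's birth/death
  rates; a single resolved tree is the default pipeline input (repeat runs
  correlate near-perfectly at these scales, consistent with the known
  insensitivity of the ranking to within-genus topology).
* For the branch- versus species-weighted comparison, "strong phylogenetic
  range structure" is instantiated as niche evolution at half the default
  rate (0.25); the advantage of branch weighting grows as the rate drops.

## Known limitations

* The exact greedy scales as O(features × cells²); landscapes far beyond
  ~10⁴ cells would need the batched-removal acceleration that real Zonation
  uses.
* The logistic scorer is linear in the predictors; strongly multimodal
  niches would need the richer model ensemble that real applications use.
  Everything asserted about the chain (TSS filtering, ensembling,
  thresholding, clipping, dispersal) is independent of that choice.
* Range areas are cell counts × cell area; partial occupancy within a cell
  is not represented.
* Costs are uniform in the headline runs; per-cell cost (e.g. HMI as cost)
  is exposed but unexercised by default.
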