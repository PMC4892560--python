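# Methods

This note documents the models and procedures implemented in `pieces`,
the parameter choices that matter, and what the synthetic-data tests do
and do not demonstrate.

## Evolutionary distinctiveness

`fair_proportion` implements the fair-proportion partition: every edge's
length is divided equally among the tips descending from it and a tip's
ED is the sum of its shares along the root-to-tip path. The root edge
(when the Newick carries one) is excluded — it is shared by all tips and
carries no information about distinctiveness. Consequently Σ ED over
tips equals the tree's total branch length, an identity the tests check
to 1e-6 relative error.

Polytomies inflate fair-proportion ED: an unresolved node treats its
daughters as splitting at the same instant, crediting each with more
exclusive history than a resolved topology would. The correction used
here (`ed_with_polytomy_correction`) multiplies the length of every edge
descending from a node with c children by 2/c before the partition. The
factor is 1 at bifurcations — so the corrected values coincide exactly
with fair proportion on fully resolved trees — and strictly discounts
polytomy daughters, the two properties any such correction must have.
It is the package's own documented choice: published descriptions of
polytomy corrections for ED name the idea without giving an algebraic
form, and no reference implementation is available in this environment
to calibrate against. The correction defaults to on when the input tree
contains polytomies (`compute_ed`), and is sensitivity-tested rather
than treated as exact.

## Phylogenetic signal: the D statistic

For a binary trait on a rooted tree, the raw statistic Σd accumulates,
over internal nodes, the absolute deviations of each child's estimated
value from the node's estimate, where a node's estimate is the plain
mean of its children's values (computed tips-to-root). For a
bifurcation this is |left − right|; polytomies contribute the summed
deviations from the mean of all children, which reduces to the
bifurcating rule and makes the statistic well defined on poorly
resolved trees. Nodal estimation deliberately uses unit branch lengths;
the Brownian null uses the tree's real lengths. Because

D = (Σd_obs − mean Σd_Brownian) / (mean Σd_random − mean Σd_Brownian)

is a ratio of differences under an identical Σd scheme, any affine
rescaling of the scheme cancels; the tests confirm D is invariant to
multiplying all branch lengths by a constant.

Nulls (n_perm each, default 1000): *random* = the observed values
shuffled across tips; *Brownian-threshold* = a continuous character with
independent N(0, edge-length) increments per edge, binarized by ranking
so that exactly the observed number of tips get 1 (exact prevalence
conditioning; a fixed cut value would let prevalence drift). One-sided
p-values: p_random = P(Σd_null ≤ Σd_obs) tests departure from
randomness (D < 1); p_brownian = P(Σd_null ≥ Σd_obs) tests departure
from Brownian clustering (D > 0).

Calibration on a 128-tip Yule tree (100 traits × 100 permutations):
mean D over permutation-generated traits falls in [0.85, 1.15] and over
Brownian-threshold traits in [−0.15, 0.15]; p_random is approximately
uniform under its null (KS test). On a perfect star Σd depends only on
prevalence, both nulls coincide and D is undefined; `d_statistic`
raises rather than returning noise, and the resolution-sensitivity
sweep (`resolution_sensitivity`, collapse-then-retest over ascending
thresholds) is therefore exercised short of the star. On strongly
clustered traits the estimated D drifts toward 1 and detection power
decays as resolution is collapsed away — the qualitative behavior
expected when topology stops carrying signal.

## Trees

Newick I/O is delegated to dendropy (quoted labels, internal labels and
bracket comments accepted; missing lengths filled with a configurable
default, 0 by default). Grafting attaches each new taxon as a child of
its genus's crown node (MRCA of the congeners) with terminal branch
length equal to the crown depth, defined as the maximum
node-to-descendant-tip distance so the rule is total on non-ultrametric
inputs; on ultrametric trees this preserves ultrametricity exactly. A
genus represented by one tip is handled by bisecting that tip's
terminal edge (preserving genus monophyly); the alternative
family-crown fallback is available via `singleton_policy="family"`.
Taxa with no congeners attach at the family crown. Pruning suppresses
degree-2 nodes with branch-length summation, so kept tips retain their
root-to-tip depths. `collapse_short_edges` removes internal edges
strictly shorter than the threshold and reattaches grandchildren with
their own lengths unchanged (di2multi semantics — the operation acts on
internal edges, never deletes tips), which makes it idempotent and
resolution monotone non-increasing in the threshold. Resolution is
internal-node count over n_tips − 1.

## Scores and normalizations

Collection deficits use 1 − ln(x+1)/ln(max+1) with the maximum taken
over the **full candidate table** (never a selected subset), recomputed
per input; if every count is zero all deficits are 1 by convention. ED
enters PIECES min–max scaled over the same pool ("scaled from 0 to 1"
read as min–max; a max-only scaling would differ only by an affine map
of the ED column). The EDGE comparison score is
ln(1 + ED_raw) + GE_level·ln 2 with GE_level integer 4…0 for R1…R5 —
the 0–4 scale mirrors the threat axis used for mean-threat ROI,
extended to secure taxa at 0. Selection ties are broken by ascending
taxon label; the choice is arbitrary but documented and makes every
deterministic pipeline byte-reproducible.

## Decision layer

AHP weights are the principal right eigenvector of the reciprocal
comparison matrix, computed by power iteration (tolerance 1e-12, cap
10,000 iterations, dense eigendecomposition as fallback) and normalized
to sum 1; λmax is evaluated at the fixed point. CR uses Saaty's random
index (n = 1–10 hard-coded); CR > 0.1 warns but never blocks — the
framework treats weights as the decision maker's statement, not a
hypothesis to reject.

Scheme families: Endangered fills whole threat strata in rank order and
uniformly samples the stratum that straddles n; ExSitu uniformly
samples taxa absent from both collection types. Both report mean ROI
over n_subsamples replicates (default 1000). Weight-space analysis
samples weight vectors from the flat Dirichlet (uniform on the
simplex), scores, selects top-n with the same stable tie rule, and
records the four ROI objectives per vector. Pareto frontiers use a
sort-and-sweep filter verified against exhaustive O(k²) dominance
checking; orientation is maximize on all four ROI objectives. The gap
table is the 4 (seed-only / living-only / both / neither) × 5 (R1–R5)
contingency table with Pearson's X² (no continuity correction,
all-zero rows/columns dropped). Solution similarity is Jaccard on
labels and PhyloSor on branch lengths, the latter under the
root-spanning convention (spanning paths run to the root, root edge
excluded) — stated explicitly because the MRCA-spanning convention
gives different values. For scheme families, family-vs-single
similarities average over the family's first 100 replicates and
family-vs-family pairs replicates elementwise.

## Synthetic data

`yule_tree` draws a pure-birth tree (exponential waiting times, uniform
lineage choice, branches extended to the present), giving an
ultrametric, fully bifurcating phylogeny. `synth_taxon_table` builds the
latent threat trait `signal_strength · Z_Brownian(standardized) +
N(0,1)` and cuts it by rank order into exact rank quotas (quota
thresholding removes binomial noise from rank counts, a deliberate
anti-flakiness choice); collection counts are zero-inflated geometric —
a structural zero with a per-rank probability, otherwise a geometric
draw (support ≥ 1) with a per-rank mean.

`paper_shaped_fixture` (500 tips by default — large enough for stable
scheme behavior, small enough that the whole suite runs in seconds)
fixes rank proportions to the published totals of the North American
angiosperm assessment (7.9 / 10.8 / 17.9 / 29.7 / 33.7% for R1–R5) and
per-rank zero-inflation to the published status-by-rank prevalences, so
the overall marginals land at ≈ 34% seed-banked and ≈ 49% in living
collections. Nonzero count means (2–5 seed, 3–8 living, rising toward
secure ranks) and signal_strength = 1.0 (moderate clustering of threat
ranks) are one-time realism choices. What the generator does **not**
emulate: dependence between seed and living status within a taxon (they
are conditionally independent given rank, whereas real coverage types
co-occur), clustering of collection status beyond what threat-rank
clustering induces, realistic taxonomy, and heavy-tailed count extremes.
Tests passing on this fixture therefore validate the machinery and its
calibration, not empirical claims about real collections.

## Numerical notes

All randomness flows through `numpy.random.default_rng` with explicit
seeds; scheme families, sweeps and pipelines derive child seeds via
`SeedSequence` where needed and are byte-reproducible. Branch lengths
are accepted at 0 (Brownian simulation falls back to unit lengths only
when a tree carries no length information at all). Degenerate inputs
raise typed errors (`TraitError`, `TableError`, `MatrixError`,
`TreeStructureError`, `GraftError`) rather than propagating NaNs:
constant traits, all-equal ED vectors, non-reciprocal matrices, star
trees in `d_statistic`, and table/tree tip mismatches (hard error by
default; `allow_missing_tips` drops with a logged count, because a
silent mismatch would corrupt ED and PhyloSor).
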