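# pieces

Phylogenetically informed prioritization of species for *ex situ*
conservation.

Seed banks and living collections cannot hold everything, so curators
must decide which species to add next. Optimizing a single criterion —
most threatened, least collected, most evolutionarily distinct — yields
very different (and mutually exclusive) portfolios. `pieces` implements
a multi-criteria framework for this decision, aimed at conservation
scientists and collection managers working with a phylogeny plus a
table of threat ranks and collection counts.

## The score

Each candidate taxon receives

```
PIECES = 100 · (w₁·SB + w₂·LC + w₃·GE + w₄·ED)
```

where all components lie in [0, 1] and the non-negative weights sum
to 1:

* **SB, LC** — seed-bank and living-collection *deficits*:
  `1 − ln(count + 1)/ln(max count + 1)` (1 = uncollected, 0 = the
  most-collected taxon; the log captures diminishing returns of extra
  accessions).
* **GE** — threat rank mapped R1 → 1, R2 → 0.75, R3 → 0.5, R4 → 0.25,
  R5 → 0 (NatureServe-style, R1 = critically imperiled).
* **ED** — fair-proportion evolutionary distinctiveness (each branch's
  length split equally among its descendant tips), min–max scaled;
  an optional polytomy correction discounts the ED inflation caused by
  unresolved nodes.

Weights come from pairwise comparisons via the Analytic Hierarchy
Process (normalized principal eigenvector, with consistency ratio); the
reference weight set elicited for North American angiosperms,
`(0.4623, 0.0771, 0.1979, 0.2627)`, ships as
`pieces.PUBLISHED_WEIGHTS`.

Around the score the package provides: the Fritz–Purvis **D statistic**
for phylogenetic signal of binary traits (permutation and
Brownian-threshold nulls, plus a resolution-sensitivity sweep);
alternative schemes (Endangered, ExSitu, ED + Seed Bank, EDGE);
return-on-investment metrics, 4-D weight-space analysis and Pareto
frontiers; gap tables with chi-squared; Jaccard/PhyloSor similarity of
selected sets; tree machinery (Newick I/O, crown grafting, pruning,
short-edge collapse); and a synthetic fixture generator.

## Worked example

```python
import pieces

tree, table = pieces.paper_shaped_fixture(seed=1)   # 500-taxon fixture
ed = pieces.fair_proportion(tree)
scores = pieces.pieces_scores(table, pieces.PUBLISHED_WEIGHTS, ed)
print(scores.sort_values("pieces", ascending=False).head(3).to_string(index=False))
```

```
taxon       sb  lc    ge       ed    pieces
t0259  1.0  1.0  0.75  0.840  90.85
t0001  1.0  1.0  0.75  0.677  86.56
t0077  1.0  1.0  0.75  0.581  84.04
```

The top taxa are absent from all collections (SB = LC = 1), threatened
(R2, GE = 0.75) and evolutionarily distinct — the profile the weighted
sum is designed to surface. `examples/` contains one short script per
capability (scoring, signal testing, AHP, ROI trade-offs, tree
surgery); each prints its numbers with a line on what they mean. A thin
CLI (`pieces simulate|score|signal-d|ahp|roi|weightspace|pareto|gaps|
compare|reproduce ...`) wraps the same functions for shell use.

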