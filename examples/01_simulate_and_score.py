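"""Simulate a taxon pool and rank it with the PIECES score.

Builds the 500-taxon synthetic fixture (ultrametric tree + threat ranks
+ collection counts), computes fair-proportion evolutionary
distinctiveness, and scores every taxon with the published preference
weights (SB 0.4623, LC 0.0771, GE 0.1979, ED 0.2627).
"""

import pieces

tree, table = pieces.paper_shaped_fixture(seed=1)
ed = pieces.fair_proportion(tree)
scores = pieces.pieces_scores(table, pieces.PUBLISHED_WEIGHTS, ed)

top = scores.sort_values("pieces", ascending=False).head(5)
print(top.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print()
print(
    "Each row shows the four normalized criteria (sb/lc/ge/ed, all in"
    " [0,1])\nand the PIECES score in [0,100]: the top taxa are uncollected"
    " (sb = lc = 1),\nhighly threatened and evolutionarily distinct —"
    " exactly the profile the\nweighted sum is meant to surface first."
)
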