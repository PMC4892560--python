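"""Tree assembly and resolution: graft, prune, collapse.

Shows the supertree-style machinery: grafting unsampled taxa at their
genus (or family) crown keeps an ultrametric tree ultrametric; pruning
preserves root-to-tip depths; collapsing short internal edges degrades
resolution toward a star.
"""

import pieces
from pieces import GraftAssignment

tree = pieces.read_newick(
    "((Quercus_alba:20,Quercus_rubra:20):30,(Acer_rubrum:35,Acer_negundo:35):15);"
)
genus = {t: t.split("_")[0] for t in pieces.tip_labels(tree)}
genus |= {"Quercus_bicolor": "Quercus", "Ulmus_americana": "Ulmus"}
family = {t: ("Fagaceae" if g == "Quercus" else "Sapindaceae")
          for t, g in genus.items()}
family["Ulmus_americana"] = "Sapindaceae"  # pretend, to exercise the fallback

grafted = pieces.graft_taxa(
    tree,
    [GraftAssignment("Quercus_bicolor", "Quercus", "Fagaceae"),
     GraftAssignment("Ulmus_americana", "Ulmus", "Sapindaceae")],
    genus, family,
)
print("after grafting:", pieces.write_newick(grafted))
print("still ultrametric:", pieces.is_ultrametric(grafted))
print("resolution:", round(pieces.resolution(grafted), 3))

pruned = pieces.prune(grafted, {"Quercus_alba", "Acer_rubrum"})
print("\npruned to 2 tips:", pieces.write_newick(pruned))
print("depths preserved:", pieces.tip_depths(pruned))

collapsed = pieces.collapse_short_edges(grafted, 100.0)
print("\nfully collapsed resolution:", round(pieces.resolution(collapsed), 3))
print()
print(
    "Quercus_bicolor joins the Quercus crown at the genus crown depth (a\n"
    "polytomy); Ulmus, with no congeners, attaches at its family's crown.\n"
    "Collapsing all internal edges leaves the star tree, resolution\n"
    "1/(n-1)."
)
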