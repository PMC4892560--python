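"""End-to-end driver: from a tree + taxon table to all prioritization
artifacts (scores, ROI, weight-space cloud, similarity matrices, gap
table) with a machine-readable run manifest.

Used by the ``pieces reproduce`` CLI command; importable directly for
scripted runs.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import TableError
from .mcda import (
    SCHEMES,
    compare_solutions,
    gap_table,
    mean_roi,
    roi,
    scheme_selection,
    weight_space_analysis,
)
from .phylodiv import ed_with_polytomy_correction, fair_proportion
from .scoring import PUBLISHED_WEIGHTS, edge_scores, pieces_scores, validate_table
from .treeio import read_newick, resolution, tip_labels

__all__ = ["RunConfig", "run_pipeline", "align_table_to_tree", "compute_ed"]


@dataclass
class RunConfig:
    """Configuration of a full prioritization run."""

    tree_path: str | None = None
    table_path: str | None = None
    out_dir: str = "pieces_out"
    weights: tuple = PUBLISHED_WEIGHTS
    n_select: int = 100
    n_subsamples: int = 100
    k_weight_vectors: int = 1000
    n_compare_draws: int = 100
    seed: int = 0
    isaac_correction: bool | None = None  # None = auto (on iff polytomies)
    allow_missing_tips: bool = False


def align_table_to_tree(table: pd.DataFrame, tree, allow_missing: bool = False):
    """Check table taxa against tree tips; optionally drop the absent ones.

    A taxon in the table but not in the tree would silently corrupt ED
    and PhyloSor, so it is a hard error unless ``allow_missing``.
    Returns (table restricted to tree tips, number dropped).
    """
    table = validate_table(table)
    tips = set(tip_labels(tree))
    missing = [t for t in table["taxon"] if t not in tips]
    if missing and not allow_missing:
        raise TableError(
            f"{len(missing)} table taxa absent from tree, e.g. {missing[:5]}"
        )
    kept = table[table["taxon"].isin(tips)].reset_index(drop=True)
    return kept, len(missing)


def compute_ed(tree, isaac_correction: bool | None = None) -> pd.Series:
    """Raw ED per tip; with ``None`` the polytomy correction switches on
    automatically when the tree contains polytomies."""
    if isaac_correction is None:
        isaac_correction = any(
            len(nd.child_nodes()) > 2 for nd in tree.preorder_internal_node_iter()
        )
    if isaac_correction:
        return ed_with_polytomy_correction(tree, correction=True)
    return fair_proportion(tree)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, tree=None, table=None) -> dict:
    """Run the full analysis and write all artifacts under ``out_dir``.

    ``tree``/``table`` may be passed in-memory; otherwise they are read
    from the configured paths. Writes scores.csv, roi.csv, cloud.csv,
    similarity_jaccard.csv, similarity_phylosor.csv, gap_table.csv and
    manifest.json; returns the manifest dict. Reruns with identical
    config and inputs produce identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "config": {
            k: (round(v, 6) if isinstance(v, float) else v)
            for k, v in asdict(config).items()
        },
        "inputs": {},
    }
    if tree is None:
        if config.tree_path is None:
            raise ValueError("no tree given: set tree_path or pass tree=")
        manifest["inputs"]["tree_sha256"] = _sha256(Path(config.tree_path))
        tree = read_newick(Path(config.tree_path).read_text())
    if table is None:
        if config.table_path is None:
            raise ValueError("no table given: set table_path or pass table=")
        manifest["inputs"]["table_sha256"] = _sha256(Path(config.table_path))
        table = pd.read_csv(config.table_path)

    table, n_dropped = align_table_to_tree(table, tree, config.allow_missing_tips)
    manifest["n_taxa"] = int(len(table))
    manifest["n_dropped_missing_tips"] = n_dropped
    manifest["tree_resolution"] = round(resolution(tree), 6)

    ed = compute_ed(tree, config.isaac_correction)
    weights = tuple(round(float(w), 6) for w in config.weights)
    manifest["resolved_weights"] = weights
    manifest["normalization"] = {
        "max_n_seed": int(table["n_seed"].max()),
        "max_n_living": int(table["n_living"].max()),
        "ed_min": round(float(ed.loc[table["taxon"]].min()), 6),
        "ed_max": round(float(ed.loc[table["taxon"]].max()), 6),
    }

    scores = pieces_scores(table, config.weights, ed)
    scores["edge"] = edge_scores(table, ed).to_numpy()
    scores.to_csv(out / "scores.csv", index=False)

    selections = {}
    roi_rows = []
    for scheme in SCHEMES:
        sel = scheme_selection(
            scheme,
            table,
            ed,
            n=config.n_select,
            weights=config.weights,
            n_subsamples=config.n_subsamples,
            seed=config.seed,
        )
        selections[scheme] = sel
        record = mean_roi(sel, table, ed) if isinstance(sel[0], list) else roi(sel, table, ed)
        roi_rows.append({"scheme": scheme, **asdict(record)})
    pd.DataFrame(roi_rows).to_csv(out / "roi.csv", index=False)

    cloud = weight_space_analysis(
        table, ed, k=config.k_weight_vectors, n=config.n_select, seed=config.seed
    )
    cloud.to_csv(out / "cloud.csv", index=False)

    jac, phy = compare_solutions(selections, tree, n_draws=config.n_compare_draws)
    jac.to_csv(out / "similarity_jaccard.csv")
    phy.to_csv(out / "similarity_phylosor.csv")

    counts, chi2, p = gap_table(table)
    counts.to_csv(out / "gap_table.csv")
    manifest["gap_chi2"] = round(chi2, 6)
    manifest["gap_p"] = float(p)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
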