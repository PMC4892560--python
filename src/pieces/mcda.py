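"""Multi-criteria decision analysis for conservation prioritization.

This module covers the decision layer around the PIECES score:

* AHP weight elicitation — weights are the normalized principal right
  eigenvector of a reciprocal pairwise-comparison matrix (Saaty scale
  1–9), with the consistency ratio CR = ((λmax − n)/(n − 1)) / RI(n).
* Five prioritization schemes: threat rank alone (Endangered), absence
  from all collections (ExSitu), ED among unbanked taxa (EDSeedBank),
  the EDGE score, and PIECES. The first two admit many equivalent
  solutions and are represented by families of random subsamples.
* Return on investment (ROI) of a selected set: novel seed-bank and
  living-collection additions, mean threat level (R1→4 … R5→0) and mean
  raw ED.
* Weight-space analysis (ROI over weight vectors sampled uniformly on
  the simplex), Pareto frontiers of objective pairs, the
  collection-status × threat-rank gap table with Pearson's chi-squared,
  and pairwise taxonomic (Jaccard) / phylogenetic (PhyloSor) similarity
  of scheme solutions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._arrays import TreeArrays
from .errors import MatrixError, TableError
from .phylodiv import _spanning_edge_mask, jaccard_similarity
from .scoring import (
    GE_LEVEL,
    component_matrix,
    edge_scores,
    pieces_scores,
    rank_select,
    validate_table,
)

__all__ = [
    "AHPResult",
    "ROIRecord",
    "SCHEMES",
    "ahp_weights",
    "scheme_selection",
    "roi",
    "mean_roi",
    "sample_weight_vectors",
    "weight_space_analysis",
    "pareto_front",
    "gap_table",
    "compare_solutions",
]

SCHEMES = ("Endangered", "ExSitu", "EDSeedBank", "EDGE", "PIECES")

#: Saaty's random consistency index, indexed by matrix order n = 1..10.
_RANDOM_INDEX = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12,
                 6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49}


@dataclass(frozen=True)
class AHPResult:
    weights: np.ndarray
    lambda_max: float
    consistency_ratio: float


@dataclass(frozen=True)
class ROIRecord:
    """Objective values achieved by a selected taxon set."""

    new_seed: float
    new_living: float
    mean_threat: float
    mean_ed: float


def _validate_pairwise(matrix, saaty: bool = False) -> np.ndarray:
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise MatrixError("pairwise matrix must be square")
    n = a.shape[0]
    if n < 2:
        raise MatrixError("pairwise matrix needs n >= 2")
    if (a <= 0).any():
        raise MatrixError("pairwise entries must be positive")
    if not np.allclose(np.diag(a), 1.0, atol=1e-9):
        raise MatrixError("pairwise diagonal must be 1")
    if not np.allclose(a * a.T, 1.0, atol=1e-9):
        raise MatrixError("matrix is not reciprocal (a_ji != 1/a_ij)")
    if saaty and ((a < 1 / 9 - 1e-9) | (a > 9 + 1e-9)).any():
        raise MatrixError("entries outside the Saaty 1/9..9 scale")
    return a


def ahp_weights(matrix, saaty: bool = False, tol: float = 1e-12,
                max_iter: int = 10_000) -> AHPResult:
    """AHP weights from a reciprocal pairwise-comparison matrix.

    Weights are the principal right eigenvector (positive by
    Perron–Frobenius) normalized to sum 1, computed by power iteration
    with a dense-eigendecomposition fallback; λmax is the dominant
    eigenvalue. A consistency ratio above 0.1 triggers a warning but is
    never enforced.
    """
    a = _validate_pairwise(matrix, saaty=saaty)
    n = a.shape[0]
    v = np.ones(n) / n
    converged = False
    for _ in range(max_iter):
        nxt = a @ v
        nxt /= nxt.sum()
        if np.abs(nxt - v).max() < tol:
            v = nxt
            converged = True
            break
        v = nxt
    if not converged:  # pragma: no cover - power iteration converges on positives
        eigvals, eigvecs = np.linalg.eig(a)
        idx = int(np.argmax(eigvals.real))
        v = np.abs(eigvecs[:, idx].real)
        v /= v.sum()
    lambda_max = float((a @ v).sum())  # since v sums to 1
    if n in _RANDOM_INDEX and _RANDOM_INDEX[n] > 0:
        cr = ((lambda_max - n) / (n - 1)) / _RANDOM_INDEX[n]
    else:
        cr = 0.0
    cr = float(max(cr, 0.0))
    if cr > 0.1:
        warnings.warn(f"AHP consistency ratio {cr:.3f} exceeds 0.1", stacklevel=2)
    return AHPResult(weights=v, lambda_max=lambda_max, consistency_ratio=cr)


# ----------------------------------------------------------------------
# prioritization schemes & ROI


def _ed_series(table: pd.DataFrame, ed) -> pd.Series:
    if ed is None:
        if "ed" not in table.columns:
            raise TableError("raw ED required: pass ed= or include an 'ed' column")
        return pd.Series(table["ed"].to_numpy(), index=table["taxon"].to_numpy())
    ed = pd.Series(ed)
    missing = set(table["taxon"]) - set(ed.index)
    if missing:
        raise TableError(f"ed missing for taxa, e.g. {sorted(missing)[:3]}")
    return ed


def scheme_selection(
    scheme: str,
    table: pd.DataFrame,
    ed=None,
    n: int = 1000,
    weights=None,
    n_subsamples: int = 1000,
    seed: int = 0,
):
    """Select ``n`` taxa under a prioritization scheme.

    Deterministic schemes (PIECES, EDGE, EDSeedBank) return a single
    list of taxon labels. Degenerate schemes (Endangered, ExSitu) have
    many equivalent optima and return ``n_subsamples`` lists of
    uniformly sampled solutions. ``weights`` is required for PIECES.
    """
    table = validate_table(table)
    if n > len(table):
        raise ValueError(f"cannot select {n} of {len(table)} taxa")
    if scheme == "PIECES":
        if weights is None:
            raise ValueError("PIECES scheme requires weights")
        scored = pieces_scores(table, weights, ed)
        return rank_select(
            pd.Series(scored["pieces"].to_numpy(), index=scored["taxon"].to_numpy()), n
        )
    if scheme == "EDGE":
        return rank_select(edge_scores(table, ed), n)
    if scheme == "EDSeedBank":
        ed_s = _ed_series(table, ed)
        pool = table.loc[table["n_seed"] == 0, "taxon"]
        if len(pool) < n:
            raise ValueError(
                f"EDSeedBank pool has {len(pool)} unbanked taxa; need {n}"
            )
        return rank_select(ed_s.loc[pool.to_numpy()], n)
    if scheme in ("Endangered", "ExSitu"):
        rng = np.random.default_rng(seed)
        if scheme == "ExSitu":
            pool = table.loc[
                (table["n_seed"] == 0) & (table["n_living"] == 0), "taxon"
            ].to_numpy()
            if len(pool) < n:
                raise ValueError(
                    f"ExSitu pool has {len(pool)} uncollected taxa; need {n}"
                )
            fixed, variable, n_var = [], pool, n
        else:
            # fill whole strata in threat order; sample only the stratum
            # that straddles the cutoff
            fixed, variable, n_var = [], None, n
            for rank in ("R1", "R2", "R3", "R4", "R5"):
                stratum = table.loc[table["rank"] == rank, "taxon"].to_numpy()
                if len(stratum) <= n_var:
                    fixed.extend(stratum)
                    n_var -= len(stratum)
                    if n_var == 0:
                        variable = np.array([], dtype=stratum.dtype)
                        break
                else:
                    variable = stratum
                    break
            if variable is None:
                raise ValueError("candidate pool smaller than n")
        out = []
        for _ in range(n_subsamples):
            drawn = rng.choice(variable, size=n_var, replace=False) if n_var else []
            out.append(sorted([*fixed, *drawn]))
        return out
    raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")


def roi(selection: Sequence[str], table: pd.DataFrame, ed=None) -> ROIRecord:
    """ROI of one selected taxon set (see :class:`ROIRecord`)."""
    table = validate_table(table)
    ed_s = _ed_series(table, ed)
    sub = table.set_index("taxon")
    unknown = set(selection) - set(sub.index)
    if unknown:
        raise TableError(f"selection contains unknown taxa, e.g. {sorted(unknown)[:3]}")
    sel = sub.loc[list(selection)]
    return ROIRecord(
        new_seed=int((sel["n_seed"] == 0).sum()),
        new_living=int((sel["n_living"] == 0).sum()),
        mean_threat=float(sel["rank"].map(GE_LEVEL).mean()),
        mean_ed=float(ed_s.loc[list(selection)].mean()),
    )


def mean_roi(selections: Sequence[Sequence[str]], table: pd.DataFrame, ed=None) -> ROIRecord:
    """Mean ROI across a family of equivalent solutions."""
    records = [roi(sel, table, ed) for sel in selections]
    return ROIRecord(
        new_seed=float(np.mean([r.new_seed for r in records])),
        new_living=float(np.mean([r.new_living for r in records])),
        mean_threat=float(np.mean([r.mean_threat for r in records])),
        mean_ed=float(np.mean([r.mean_ed for r in records])),
    )


# ----------------------------------------------------------------------
# weight space & Pareto


def sample_weight_vectors(k: int, dims: int = 4, seed: int = 0) -> np.ndarray:
    """k weight vectors sampled uniformly on the (dims−1)-simplex
    (flat Dirichlet); rows sum to 1. Deterministic under ``seed``."""
    if k < 1 or dims < 2:
        raise ValueError("need k >= 1 and dims >= 2")
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.ones(dims), size=k)


def weight_space_analysis(
    table: pd.DataFrame,
    ed=None,
    k: int = 100_000,
    n: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """ROI achieved by the top-``n`` PIECES selection under ``k`` random
    weight vectors.

    Returns a DataFrame pairing each weight vector (columns w1..w4) with
    its ROI (new_seed, new_living, mean_threat, mean_ed). Selection uses
    the same descending-score, tie-by-label rule as :func:`rank_select`.
    """
    table = validate_table(table)
    if n > len(table):
        raise ValueError(f"cannot select {n} of {len(table)} taxa")
    comp = component_matrix(table, ed)
    m = comp[["sb", "lc", "ge", "ed"]].to_numpy()
    ed_raw = _ed_series(table, ed).loc[table["taxon"].to_numpy()].to_numpy(dtype=float)
    zero_seed = (table["n_seed"] == 0).to_numpy()
    zero_living = (table["n_living"] == 0).to_numpy()
    threat = table["rank"].map(GE_LEVEL).to_numpy(dtype=float)

    ws = sample_weight_vectors(k, dims=4, seed=seed)
    rows = np.empty((k, 4))
    for i in range(k):
        scores = m @ ws[i]
        # table rows are label-sorted, so a stable sort breaks ties by label
        top = np.argsort(-scores, kind="stable")[:n]
        rows[i] = (
            zero_seed[top].sum(),
            zero_living[top].sum(),
            threat[top].mean(),
            ed_raw[top].mean(),
        )
    out = pd.DataFrame(ws, columns=["w1", "w2", "w3", "w4"])
    out[["new_seed", "new_living", "mean_threat", "mean_ed"]] = rows
    return out


def pareto_front(points, orientation: tuple[str, str] = ("max", "max")) -> np.ndarray:
    """Non-dominated subset of 2-D points.

    ``orientation`` gives the preferred direction per axis ("max" or
    "min"). A point is dominated when another is at least as good on
    both axes and strictly better on one. Duplicate frontier points are
    returned once, sorted by the first axis.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
        raise ValueError("points must be a non-empty (k, 2) array")
    if len(orientation) != 2 or any(o not in ("max", "min") for o in orientation):
        raise ValueError("orientation must be two of 'max'/'min'")
    sign = np.array([1.0 if o == "max" else -1.0 for o in orientation])
    work = np.unique(pts * sign, axis=0)  # sorted ascending by x then y
    keep = []
    best_y = -np.inf
    for x, y in work[::-1]:  # descending x
        if y > best_y:
            keep.append((x, y))
            best_y = y
    front = np.array(keep[::-1]) * sign
    return front[np.argsort(front[:, 0])]


# ----------------------------------------------------------------------
# gap analysis & solution comparison


def gap_table(table: pd.DataFrame):
    """Collection status × threat rank contingency table with Pearson X².

    Rows: taxa in seed banks only, living collections only, both, or
    neither; columns: ranks R1–R5. Returns (counts DataFrame, X²,
    p-value). X² uses independence expectations without continuity
    correction; all-zero rows/columns are dropped from the test.
    """
    table = validate_table(table)
    if table.empty:
        raise TableError("gap_table requires a non-empty table")
    seed = table["n_seed"] > 0
    living = table["n_living"] > 0
    status = np.select(
        [seed & ~living, ~seed & living, seed & living],
        ["seed_only", "living_only", "both"],
        default="neither",
    )
    counts = (
        pd.crosstab(pd.Series(status, name="status"), table["rank"])
        .reindex(index=["seed_only", "living_only", "both", "neither"], fill_value=0)
        .reindex(columns=list(GE_LEVEL), fill_value=0)
    )
    obs = counts.to_numpy()
    nz = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if min(nz.shape) < 2:
        return counts, 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(nz, correction=False)
    return counts, float(chi2), float(p)


def _as_family(selection) -> list[list[str]]:
    if len(selection) and isinstance(selection[0], str):
        return [list(selection)]
    return [list(s) for s in selection]


def compare_solutions(
    selections: Mapping[str, Sequence],
    tree,
    n_draws: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise taxonomic (Jaccard) and phylogenetic (PhyloSor)
    similarity between scheme solutions.

    Each value of ``selections`` is either a single selection (list of
    labels) or a family of equivalent selections; families contribute
    the mean similarity over their first ``n_draws`` replicates, paired
    elementwise when both sides are families. Returns two symmetric
    DataFrames with unit diagonal.
    """
    if len(selections) < 2:
        raise ValueError("need at least two selections to compare")
    ta = TreeArrays(tree)
    names = list(selections)
    fams = {name: _as_family(selections[name])[:n_draws] for name in names}
    masks = {
        name: [_spanning_edge_mask(ta, sel) for sel in fam]
        for name, fam in fams.items()
    }
    bl = {
        name: [float(ta.length[mk].sum()) for mk in mks]
        for name, mks in masks.items()
    }
    jac = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    phy = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            fa, fb = fams[a], fams[b]
            if len(fa) > 1 and len(fb) > 1:
                k = min(len(fa), len(fb))
                pairs = [(j, j) for j in range(k)]
            else:
                pairs = [(ia, ib) for ia in range(len(fa)) for ib in range(len(fb))]
            jvals, pvals = [], []
            for ia, ib in pairs:
                jvals.append(jaccard_similarity(fa[ia], fb[ib]))
                shared = float(ta.length[masks[a][ia] & masks[b][ib]].sum())
                pvals.append(2.0 * shared / (bl[a][ia] + bl[b][ib]))
            jac.loc[a, b] = jac.loc[b, a] = float(np.mean(jvals))
            phy.loc[a, b] = phy.loc[b, a] = float(np.mean(pvals))
    return jac, phy
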