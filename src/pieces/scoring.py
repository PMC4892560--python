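"""Component normalizations and priority scores.

The PIECES score combines four criteria, each normalized to [0, 1], into
a weighted sum scaled to [0, 100]:

    PIECES = 100 · (w1·SB + w2·LC + w3·GE + w4·ED)

SB and LC are *deficits* in seed-bank and living-collection coverage:
counts are log-transformed (ln(x+1)) then reverse-scaled so an
uncollected taxon scores 1 and the most-collected taxon 0. GE maps the
five threat ranks R1 (critically imperiled) … R5 (secure) to
1, 0.75, 0.5, 0.25, 0. ED is min–max scaled evolutionary
distinctiveness. Weights are non-negative and sum to 1.

The EDGE score — the classic two-factor alternative — is
ln(1 + ED_raw) + GE_level·ln 2 with GE_level on the integer scale
R1→4 … R5→0, so each step up in threat doubles (1 + ED).

Taxon tables are pandas DataFrames with columns ``taxon``, ``rank``
(R1–R5), ``n_seed``, ``n_living`` and, for scoring, an ``ed`` column of
raw ED values (or a separate Series).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import TableError

__all__ = [
    "GE_SCORE",
    "GE_LEVEL",
    "RANKS",
    "PUBLISHED_WEIGHTS",
    "normalize_collections",
    "ge_score",
    "scale_ed",
    "component_matrix",
    "pieces_scores",
    "edge_scores",
    "rank_select",
    "validate_table",
]

RANKS = ("R1", "R2", "R3", "R4", "R5")

#: GE component of PIECES: threat rank → [0, 1] score.
GE_SCORE = {"R1": 1.0, "R2": 0.75, "R3": 0.5, "R4": 0.25, "R5": 0.0}

#: Integer threat level used by the EDGE score and by mean-threat ROI
#: (4 = critically imperiled … 0 = secure).
GE_LEVEL = {"R1": 4, "R2": 3, "R3": 2, "R4": 1, "R5": 0}

#: AHP-elicited preference weights (SB, LC, GE, ED) used for the
#: reference prioritization of North American angiosperms.
PUBLISHED_WEIGHTS = (0.4623, 0.0771, 0.1979, 0.2627)


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Schema-check a taxon table and return it sorted by taxon label."""
    required = {"taxon", "rank", "n_seed", "n_living"}
    missing = required - set(table.columns)
    if missing:
        raise TableError(f"taxon table missing columns: {sorted(missing)}")
    if table["taxon"].duplicated().any():
        dup = table.loc[table["taxon"].duplicated(), "taxon"].iloc[0]
        raise TableError(f"duplicate taxon {dup!r} in table")
    bad = ~table["rank"].isin(RANKS)
    if bad.any():
        raise TableError(f"unknown threat rank {table.loc[bad, 'rank'].iloc[0]!r}")
    for col in ("n_seed", "n_living"):
        if (table[col] < 0).any():
            raise TableError(f"negative count in column {col!r}")
    return table.sort_values("taxon", kind="stable").reset_index(drop=True)


def normalize_collections(counts: Sequence[int]) -> np.ndarray:
    """Log-scaled coverage deficits in [0, 1].

    deficit = 1 − ln(count + 1) / ln(max_count + 1); 1 iff uncollected,
    0 iff at the maximum count, strictly decreasing in count. When every
    count is zero all deficits are 1 by convention.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise TableError("collection counts must be non-negative")
    cmax = c.max() if c.size else 0.0
    if cmax == 0:
        return np.ones_like(c)
    return 1.0 - np.log1p(c) / np.log1p(cmax)


def ge_score(rank: str) -> float:
    """GE component for a threat rank (R1 → 1 … R5 → 0)."""
    try:
        return GE_SCORE[rank]
    except KeyError:
        raise TableError(f"unknown threat rank {rank!r}") from None


def scale_ed(ed_raw: Sequence[float]) -> np.ndarray:
    """Min–max scale raw ED to [0, 1] (least to most distinct)."""
    x = np.asarray(ed_raw, dtype=float)
    if x.size < 2 or x.max() == x.min():
        raise TableError("ED scaling needs >= 2 values with max > min")
    return (x - x.min()) / (x.max() - x.min())


def _check_weights(weights) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (4,):
        raise ValueError("weights must have length 4 (SB, LC, GE, ED)")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")
    return w


def _ed_column(table: pd.DataFrame, ed) -> np.ndarray:
    if ed is None:
        if "ed" not in table.columns:
            raise TableError("no 'ed' column in table and no ed argument given")
        return table["ed"].to_numpy(dtype=float)
    ed = pd.Series(ed)
    try:
        return ed.loc[table["taxon"]].to_numpy(dtype=float)
    except KeyError as exc:
        raise TableError(f"ed values missing for some taxa: {exc}") from None


def component_matrix(table: pd.DataFrame, ed=None) -> pd.DataFrame:
    """Normalized criteria (columns sb, lc, ge, ed) for every taxon.

    Normalization denominators (max counts, ED min/max) are taken over
    the full table, so they must be computed on the complete candidate
    pool, not a selected subset.
    """
    table = validate_table(table)
    out = pd.DataFrame({"taxon": table["taxon"]})
    out["sb"] = normalize_collections(table["n_seed"].to_numpy())
    out["lc"] = normalize_collections(table["n_living"].to_numpy())
    out["ge"] = table["rank"].map(GE_SCORE).to_numpy(dtype=float)
    out["ed"] = scale_ed(_ed_column(table, ed))
    return out


def pieces_scores(table: pd.DataFrame, weights, ed=None) -> pd.DataFrame:
    """PIECES score per taxon.

    Returns a DataFrame (sorted by taxon) with the normalized components
    ``sb``, ``lc``, ``ge``, ``ed`` and the ``pieces`` score in [0, 100].
    ``ed`` raw values come from the table's ``ed`` column or the ``ed``
    argument (a Series indexed by taxon).
    """
    w = _check_weights(weights)
    comp = component_matrix(table, ed)
    comp["pieces"] = 100.0 * (comp[["sb", "lc", "ge", "ed"]].to_numpy() @ w)
    return comp


def edge_scores(table: pd.DataFrame, ed=None) -> pd.Series:
    """EDGE score per taxon: ln(1 + ED_raw) + GE_level · ln 2."""
    table = validate_table(table)
    ed_raw = _ed_column(table, ed)
    level = table["rank"].map(GE_LEVEL).to_numpy(dtype=float)
    scores = np.log1p(ed_raw) + level * np.log(2.0)
    return pd.Series(scores, index=table["taxon"].to_numpy(), name="edge")


def rank_select(scores, n: int) -> list[str]:
    """The n taxa with highest scores, ties broken by ascending label.

    ``scores`` is a Series indexed by taxon or an iterable of
    (taxon, score) pairs. Returns labels in descending-score order.
    """
    if isinstance(scores, pd.Series):
        items = list(scores.items())
    else:
        items = list(scores)
    if n > len(items):
        raise ValueError(f"cannot select {n} of {len(items)} taxa")
    if n < 0:
        raise ValueError("n must be non-negative")
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    return [taxon for taxon, _ in items[:n]]
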