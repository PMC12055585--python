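"""Pairwise exclusivity / co-occurrence testing of driver alterations.

Every unordered pair of binary driver features is tested with a two-sided
Fisher exact test on its 2x2 contingency table; Benjamini-Hochberg
correction is applied over the whole screened family, and the direction of
association is read off the sample odds ratio (>1 co-occurrent, <1 mutually
exclusive).  Single and multiple TET2 mutations can enter the screen as two
separate, mutually exclusive features.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def fisher_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test for a 2x2 table [[a, b], [c, d]].

    Returns ``(odds_ratio, p)`` where the odds ratio is the sample estimate
    a*d / (b*c): +inf when b*c == 0 with a*d > 0, NaN when both products are
    zero.  The two-sided p sums hypergeometric probabilities not exceeding
    the observed table's probability (with a small relative tolerance on the
    comparison, the common convention).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table entries must be nonnegative")
    if not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be integers")
    t = t.astype(np.int64)
    a, b = t[0]
    c, dd = t[1]
    ad, bc = a * dd, b * c
    if bc == 0 and ad == 0:
        odds = float("nan")
    elif bc == 0:
        odds = float("inf")
    else:
        odds = ad / bc
    p = float(stats.fisher_exact(t, alternative="two-sided")[1])
    return odds, min(p, 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (q values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pairwise_screen(matrix, tet2_split: pd.Series | None = None) -> pd.DataFrame:
    """Test every unordered feature pair for exclusivity / co-occurrence.

    Parameters
    ----------
    matrix : DataFrame (features x cases, binary) or DriverMatrix
    tet2_split : optional Series case_id -> {none, single, multi}; when
        given, the TET2 row is replaced by two features TET2Single and
        TET2Multi.

    Returns a DataFrame sorted by q with one row per tested pair:
    feature_a, feature_b, the 2x2 counts (a=both, b=a only, c=b only,
    d=neither), odds ratio, p, BH q over the full family, and direction.
    """
    if hasattr(matrix, "values") and not isinstance(matrix, pd.DataFrame):
        matrix = matrix.values
    mat = matrix.astype(int)
    if tet2_split is not None and "TET2" in mat.index:
        cases = mat.columns
        status = tet2_split.reindex(cases).fillna("none")
        mat = mat.drop(index="TET2")
        mat.loc["TET2Single"] = (status == "single").astype(int).to_numpy()
        mat.loc["TET2Multi"] = (status == "multi").astype(int).to_numpy()

    keep = []
    for feat, row in mat.iterrows():
        if row.nunique() < 2:
            logger.info("skipping constant feature %s", feat)
        else:
            keep.append(feat)
    mat = mat.loc[keep]
    if len(mat) < 2:
        raise ValueError("need at least two non-constant features")

    X = mat.to_numpy()
    rows = []
    for i, j in itertools.combinations(range(len(mat)), 2):
        xi, xj = X[i].astype(bool), X[j].astype(bool)
        a = int((xi & xj).sum())
        b = int((xi & ~xj).sum())
        c = int((~xi & xj).sum())
        dd = int((~xi & ~xj).sum())
        odds, p = fisher_2x2([[a, b], [c, dd]])
        if np.isnan(odds):
            direction = "NA"
        else:
            direction = "exclusive" if odds < 1 else "co-occurrent"
        rows.append({"feature_a": mat.index[i], "feature_b": mat.index[j],
                     "a": a, "b": b, "c": c, "d": dd,
                     "odds_ratio": odds, "p": p, "direction": direction})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out = out.sort_values(["q", "p"], kind="mergesort").reset_index(drop=True)
    return out[["feature_a", "feature_b", "a", "b", "c", "d",
                "odds_ratio", "p", "q", "direction"]]
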