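"""Immune-fraction deconvolution and tumor-microenvironment clustering.

Bulk expression columns are decomposed against an LM22-style signature
matrix by nonnegative least squares with simplex renormalization — a
documented stand-in for signature-based deconvolution engines; the analysis
of interest here is the downstream clustering of the fraction profiles, not
the deconvolution machinery itself.  Fractions are z-scored per cell type
and clustered (Euclidean, complete linkage) into k TME signature groups,
whose labels are fixed by a marker rule: the B/TFH-rich cluster is TME1,
the macrophage-rich cluster TME2, the remainder (mast-cell/naive-T-rich)
TME3.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import nnls

from .association import fisher_2x2
from .defaults import TME1_MARKERS, TME2_MARKERS

logger = logging.getLogger(__name__)


def deconvolve(bulk: pd.DataFrame, signature: pd.DataFrame,
               min_gene_overlap: float = 0.5) -> pd.DataFrame:
    """Estimate cell-type fractions per sample (cases x cell types).

    Per sample, the bulk vector over shared signature genes is scaled to the
    signature's overall magnitude, solved by nonnegative least squares
    against the signature columns, and renormalized to the simplex.
    """
    if (bulk.to_numpy() < 0).any():
        raise ValueError("bulk expression must be nonnegative")
    shared = signature.index.intersection(bulk.index)
    frac = len(shared) / len(signature.index)
    if frac < min_gene_overlap:
        missing = sorted(signature.index.difference(bulk.index))
        raise ValueError(
            f"only {frac:.0%} of signature genes present in bulk; missing "
            f"e.g. {missing[:10]}")
    S = signature.loc[shared].to_numpy(dtype=float)
    target = S.sum(axis=0).mean()

    out = {}
    for sample in bulk.columns:
        b = bulk.loc[shared, sample].to_numpy(dtype=float)
        total = b.sum()
        if total > 0:
            b = b * (target / total)
        f, _ = nnls(S, b)
        if f.sum() == 0:
            raise ValueError(f"sample {sample!r} deconvolved to all-zero "
                             "fractions")
        out[sample] = f / f.sum()
    return pd.DataFrame.from_dict(out, orient="index",
                                  columns=list(signature.columns))


def cluster_tme(fractions: pd.DataFrame, k: int = 3,
                tme1_markers=TME1_MARKERS,
                tme2_markers=TME2_MARKERS) -> pd.Series:
    """Hierarchical TME clustering of immune-fraction profiles.

    Fractions are z-scored per cell type (constant types left at zero),
    clustered with Euclidean distance and complete linkage, and cut into
    ``k`` groups.  For k = 3 labels follow the marker rule (TME1 = highest
    mean B/TFH z-score, TME2 = highest macrophage z-score among the rest);
    otherwise groups are labelled TME1..TMEk by descending size.
    """
    n = len(fractions)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available cases")
    X = fractions.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    if k == 1:
        raw = np.ones(n, dtype=int)
    else:
        link = linkage(Z, method="complete", metric="euclidean")
        raw = fcluster(link, t=k, criterion="maxclust")
    zdf = pd.DataFrame(Z, index=fractions.index, columns=fractions.columns)

    ids = sorted(set(raw))
    if k == 3 and len(ids) == 3 \
            and set(tme1_markers) <= set(fractions.columns) \
            and set(tme2_markers) <= set(fractions.columns):
        mean1 = {i: zdf.loc[raw == i, list(tme1_markers)].mean().mean()
                 for i in ids}
        tme1 = max(ids, key=lambda i: mean1[i])
        rest = [i for i in ids if i != tme1]
        mean2 = {i: zdf.loc[raw == i, list(tme2_markers)].mean().mean()
                 for i in rest}
        tme2 = max(rest, key=lambda i: mean2[i])
        tme3 = next(i for i in rest if i != tme2)
        mapping = {tme1: "TME1", tme2: "TME2", tme3: "TME3"}
    else:
        sizes = {i: int((raw == i).sum()) for i in ids}
        order = sorted(ids, key=lambda i: (-sizes[i], i))
        mapping = {i: f"TME{r + 1}" for r, i in enumerate(order)}
    return pd.Series([mapping[i] for i in raw], index=fractions.index,
                     name="tme")


def crosstab_subtypes(genetic: pd.Series, tme: pd.Series):
    """Genetic-subtype x TME contingency table plus pairwise Fisher tests.

    For every pair of genetic subtypes and every TME label, a 2x2 Fisher
    test contrasts the label's frequency between the two subtypes;
    percentages are reported to one decimal.
    """
    common = genetic.index.intersection(tme.index)
    if len(common) == 0:
        raise ValueError("no overlapping cases between subtype and TME labels")
    g = genetic.loc[common]
    t = tme.loc[common]
    table = pd.crosstab(g, t)

    rows = []
    subtypes = list(table.index)
    for i, si in enumerate(subtypes):
        for sj in subtypes[i + 1:]:
            ni = int(table.loc[si].sum())
            nj = int(table.loc[sj].sum())
            for label in table.columns:
                a = int(table.loc[si, label])
                c = int(table.loc[sj, label])
                odds, p = fisher_2x2([[a, ni - a], [c, nj - c]])
                rows.append({
                    "subtype_a": si, "subtype_b": sj, "tme": label,
                    "count_a": a, "n_a": ni,
                    "count_b": c, "n_b": nj,
                    "percent_a": round(100.0 * a / ni, 1) if ni else np.nan,
                    "percent_b": round(100.0 * c / nj, 1) if nj else np.nan,
                    "odds_ratio": odds, "p": p,
                })
    return table, pd.DataFrame(rows)
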