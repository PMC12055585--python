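"""TET2 clonal-configuration calls and TET2/RHOA VAF-ratio statistics.

Comparing tumor and bone-marrow variant allele frequencies (VAFs)
distinguishes three configurations of TET2 mutations in TFH-lymphoma:
mutations confined to tumor cells, a clonal-hematopoiesis (CH) mutation
plus a tumor-restricted second hit, and purely CH-derived mutations.  The
ratio of the (maximal) TET2 tumor VAF to the RHOA hotspot VAF indexes the
expansion of TET2-mutated non-tumor cells; a median split of this ratio is
contrasted on overall survival.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PATTERNS = ("tumor_restricted", "ch_second_hit", "ch_only")


def classify_configuration(vaf_bm, detection_floor: float = 0.02) -> str:
    """Classify a case's TET2 mutations from bone-marrow VAFs.

    A mutation is bone-marrow-present when its BM VAF is at or above the
    detection floor.  All absent -> ``tumor_restricted``; all present ->
    ``ch_only``; a mix -> ``ch_second_hit``.  With no measured BM VAF the
    case is ``unclassifiable``.
    """
    v = np.asarray(vaf_bm, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return "unclassifiable"
    present = v >= detection_floor
    if not present.any():
        return "tumor_restricted"
    if present.all():
        return "ch_only"
    return "ch_second_hit"


def clonal_calls(calls: pd.DataFrame, detection_floor: float = 0.02,
                 aggregate: str = "max") -> pd.DataFrame:
    """Per-case clonal summary for TET2-mutated cases.

    Returns one row per TET2-mutated case: configuration pattern (from BM
    VAFs), aggregated TET2 tumor VAF, RHOA tumor VAF, and their ratio (NA
    when RHOA is absent or zero).
    """
    if aggregate not in ("max", "mean"):
        raise ValueError("aggregate must be 'max' or 'mean'")
    agg = np.nanmax if aggregate == "max" else np.nanmean

    tet2 = calls[(calls.feature == "TET2") & (calls.alt_class == "SNV")]
    rhoa = calls[(calls.feature == "RHOA") & (calls.alt_class == "SNV")]
    rhoa_vaf = rhoa.groupby("case_id")["vaf_tumor"].max()

    rows = []
    for cid, grp in tet2.groupby("case_id"):
        pattern = classify_configuration(grp["vaf_bm"].to_numpy(),
                                         detection_floor)
        tv = grp["vaf_tumor"].to_numpy(dtype=float)
        tet2_vaf = float(agg(tv)) if np.isfinite(tv).any() else np.nan
        rv = rhoa_vaf.get(cid, np.nan)
        if np.isfinite(rv) and rv > 0 and np.isfinite(tet2_vaf):
            ratio = tet2_vaf / rv
        else:
            ratio = np.nan
        rows.append({"case_id": cid, "pattern": pattern,
                     "tet2_vaf_tumor_max": tet2_vaf,
                     "rhoa_vaf_tumor": rv, "vaf_ratio": ratio})
    return pd.DataFrame(rows, columns=["case_id", "pattern",
                                       "tet2_vaf_tumor_max",
                                       "rhoa_vaf_tumor", "vaf_ratio"])


def vaf_ratio_split(calls: pd.DataFrame, clinical: pd.DataFrame,
                    cutoff="median", detection_floor: float = 0.02,
                    aggregate: str = "max"):
    """Median (or fixed-cutoff) split of the TET2/RHOA VAF ratio plus its
    survival contrast.

    Cases lacking a positive RHOA tumor VAF are excluded (logged).  Ratios
    strictly above the cutoff form the ``high`` group; ties go to ``low``.
    The survival contrast is a Cox fit of high vs low on the ``time`` /
    ``event`` columns of ``clinical``.

    Returns ``(per_case, fit)`` where ``per_case`` adds ``ratio_group`` and
    ``fit`` is the Cox result table (None when a group is empty or events
    are missing).
    """
    cc = clonal_calls(calls, detection_floor=detection_floor,
                      aggregate=aggregate)
    n_excluded = int(cc.vaf_ratio.isna().sum())
    if n_excluded:
        logger.info("excluding %d cases without a usable TET2/RHOA VAF ratio",
                    n_excluded)
    usable = cc.dropna(subset=["vaf_ratio"]).copy()
    if cutoff == "median":
        cut = float(usable.vaf_ratio.median()) if len(usable) else np.nan
    else:
        cut = float(cutoff)
    usable["ratio_group"] = np.where(usable.vaf_ratio > cut, "high", "low")
    out = cc.merge(usable[["case_id", "ratio_group"]], on="case_id",
                   how="left")
    out["ratio_group"] = out["ratio_group"].fillna("NA")
    out.attrs["cutoff"] = cut

    fit = None
    merged = usable.merge(clinical, on="case_id", how="inner")
    if {"high", "low"} <= set(merged.ratio_group.unique()):
        from .survival import cox_fit
        try:
            fit = cox_fit(merged.time, merged.event, merged.ratio_group,
                          reference="low")
        except Exception as exc:  # degenerate small splits
            logger.warning("VAF-ratio survival contrast failed: %s", exc)
    return out, fit
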