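"""Binary driver feature matrix construction.

Turns a long-format alteration call table into the binary gene-sample matrix
used for consensus clustering: one row per recurrent driver feature (gene,
arm-level CNA, or SV), one column per case, entry 1 if the case carries any
event of that feature. Features seen in fewer than ``min_cases`` cases are
dropped, and cases left with an all-zero column are set aside as candidates
for the driver-negative cluster C0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: MAF Variant_Classification -> consequence enum
MAF_CONSEQUENCE = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "truncating",
    "Frame_Shift_Del": "truncating",
    "Frame_Shift_Ins": "truncating",
    "Splice_Site": "truncating",
    "Nonstop_Mutation": "truncating",
}


@dataclass
class DriverMatrix:
    """Binary features x cases matrix plus bookkeeping."""

    values: pd.DataFrame  # features x cases, entries in {0, 1}
    excluded_cases: list[str] = field(default_factory=list)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def case_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature")

    @classmethod
    def from_tsv(cls, path) -> "DriverMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df.astype(int))


def build_driver_matrix(calls: pd.DataFrame, min_cases: int = 5,
                        case_ids=None) -> DriverMatrix:
    """Binarize the call table and apply the recurrence filter.

    A feature is retained when altered in at least ``min_cases`` cases
    (default 5, i.e. recurrent in more than four cases).  Multiple events of
    one feature in one case collapse to a single 1.  Cases whose column is
    all-zero after filtering — or that appear in ``case_ids`` but carry no
    calls at all — are listed in ``excluded_cases``.
    """
    if calls is None or len(calls) == 0:
        raise ValueError("empty alteration call table")
    key_cols = ["case_id", "feature", "alt_class"]
    if "variant_id" in calls.columns:
        key_cols.append("variant_id")
    n_dup = calls.duplicated(subset=key_cols).sum()
    if n_dup:
        logger.warning("collapsing %d duplicate call rows", n_dup)
        calls = calls.drop_duplicates(subset=key_cols)

    presence = (calls.groupby(["feature", "case_id"]).size()
                .unstack(fill_value=0) > 0).astype(int)
    if case_ids is not None:
        presence = presence.reindex(columns=list(case_ids), fill_value=0)

    support = presence.sum(axis=1)
    retained = support[support >= min_cases].index
    mat = presence.loc[sorted(retained)]

    col_sums = mat.sum(axis=0) if len(mat) else pd.Series(0, index=presence.columns)
    excluded = [c for c in mat.columns if col_sums.get(c, 0) == 0]
    kept_cases = [c for c in mat.columns if c not in set(excluded)]
    return DriverMatrix(values=mat[kept_cases], excluded_cases=excluded)


def split_tet2_multiplicity(calls: pd.DataFrame) -> pd.Series:
    """Classify cases as carrying no, a single, or multiple TET2 mutations.

    Counts distinct TET2 SNV/SV rows per case; ``multi`` means two or more.
    Used by the association screen, where single and multiple TET2 mutations
    act as two mutually exclusive binary features.
    """
    tet2 = calls[(calls.feature == "TET2")
                 & calls.alt_class.isin(["SNV", "SV"])]
    if "variant_id" in tet2.columns:
        counts = tet2.groupby("case_id")["variant_id"].nunique()
    else:
        counts = tet2.groupby("case_id").size()
    status = counts.map(lambda k: "multi" if k >= 2 else "single")
    all_cases = pd.Index(calls.case_id.unique())
    return status.reindex(all_cases, fill_value="none").rename("tet2_status")


def tet2_pair_spectrum(calls: pd.DataFrame) -> pd.DataFrame:
    """Consequence-pair spectrum of double-TET2-mutant cases.

    For cases with exactly two classifiable TET2 mutations (consequence
    missense or truncating), counts the unordered consequence pairs and
    reports counts and percentages (one decimal).  Rows with other/NA
    consequence are excluded from pairing (logged).  With zero double-mutant
    cases, percentages are NA.
    """
    tet2 = calls[(calls.feature == "TET2") & (calls.alt_class == "SNV")]
    classifiable = tet2[tet2.consequence.isin(["missense", "truncating"])]
    n_dropped = len(tet2) - len(classifiable)
    if n_dropped:
        logger.info("excluded %d TET2 rows with unclassifiable consequence",
                    n_dropped)

    counts = {"mis-mis": 0, "mis-trunc": 0, "trunc-trunc": 0}
    for _, grp in classifiable.groupby("case_id"):
        if len(grp) != 2:
            continue
        n_trunc = (grp.consequence == "truncating").sum()
        key = {0: "mis-mis", 1: "mis-trunc", 2: "trunc-trunc"}[n_trunc]
        counts[key] += 1

    total = sum(counts.values())
    out = pd.DataFrame({
        "pair": list(counts),
        "count": list(counts.values()),
    })
    if total:
        out["percent"] = (100.0 * out["count"] / total).round(1)
    else:
        out["percent"] = np.nan
    return out


def read_maf(path) -> pd.DataFrame:
    """Read a minimal MAF into the alteration-call schema (SNVs only)."""
    maf = pd.read_csv(path, sep="\t", comment="#")
    out = pd.DataFrame({
        "case_id": maf["Tumor_Sample_Barcode"],
        "feature": maf["Hugo_Symbol"],
        "alt_class": "SNV",
        "consequence": maf["Variant_Classification"].map(MAF_CONSEQUENCE)
        .fillna("other"),
    })
    out["variant_id"] = (
        out.feature + "_" + (out.groupby(["case_id", "feature"]).cumcount() + 1)
        .astype(str))
    out["vaf_tumor"] = maf["t_alt_count"] / (
        maf["t_alt_count"] + maf["t_ref_count"]) \
        if {"t_alt_count", "t_ref_count"} <= set(maf.columns) else np.nan
    out["vaf_bm"] = np.nan
    return out
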