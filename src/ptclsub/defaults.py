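"""Default cohort structure for the synthetic PTCL generator.

The default configuration mirrors the published structure of a 129-case
nTFHL/PTCL-NOS whole-exome cohort: three genetic subtypes C1/C2/C3 of sizes
57/28/34 plus a driver-negative cluster C0 of 10 cases, subtype-specific
driver alteration frequencies, subtype hazard ratios for overall survival
(C2 2.52 and C3 2.14 relative to C1), pathology mixtures per subtype, and
three tumor-microenvironment (TME) signature groups with a planted
TME2-vs-TME3 hazard ratio of 3.4.

Frequencies printed per subtype in the source cohort are used verbatim
(the chr5p/5q/21p/21q gains and RHOA/IDH2/CD28 contrasts between C3 and C1).
Frequencies the source reports only at the pathology level (e.g. TET2:
85.8% in AITL, 34.3% in PTCL-NOS) are composition-weighted into per-subtype
values. The remaining values are realistic defaults for the respective
subtype phenotype (C2 = aneuploid/tumor-suppressor-altered, GATA3-PTCL-like)
and are documented in docs/methods.md.
"""

from __future__ import annotations

SUBTYPES = ("C0", "C1", "C2", "C3")
PATHOLOGIES = ("AITL", "nTFHL-other", "PTCL-NOS")
TME_LABELS = ("TME1", "TME2", "TME3")

#: default cohort size and subtype split (57/28/34/10)
DEFAULT_N_CASES = 129
DEFAULT_SUBTYPE_PROPORTIONS = {
    "C1": 57 / 129,
    "C2": 28 / 129,
    "C3": 34 / 129,
    "C0": 10 / 129,
}

#: fraction of cases sampled before any treatment (109 of 129); only these
#: enter survival analyses.
DEFAULT_PRETREATMENT_FRACTION = 109 / 129

#: planted overall-survival hazard ratios by genetic subtype (C1 reference)
DEFAULT_HAZARD_RATIOS = {"C0": 1.0, "C1": 1.0, "C2": 2.52, "C3": 2.14}

#: planted hazard ratios by TME signature (TME3 reference); TME2 is the
#: macrophage-rich poor-prognosis group.
DEFAULT_TME_HAZARD_RATIOS = {"TME1": 1.0, "TME2": 3.4, "TME3": 1.0}

#: baseline (C1) exponential hazard, events per month — median OS ~35 months,
#: in line with reported AITL survival.
DEFAULT_BASELINE_HAZARD = 0.02
#: independent exponential censoring, tuned to ~40% censoring overall.
DEFAULT_CENSOR_RATE = 0.02

# ---------------------------------------------------------------------------
# Driver alteration frequencies per genetic subtype.  C0 carries no recurrent
# drivers by construction.  Feature names mix gene symbols, arm-level CNAs and
# structural variants, as in the published gene-sample matrix.
# ---------------------------------------------------------------------------
DEFAULT_DRIVER_FREQS: dict[str, dict[str, float]] = {
    "C1": {
        "TET2": 0.78, "RHOA": 0.421, "IDH2": 0.0877, "DNMT3A": 0.35,
        "TP53": 0.05, "CD28": 0.0702, "PLCG1": 0.10, "VAV1": 0.07,
        "HLA-A": 0.05, "NFKBIZ_SV": 0.02,
        "chr1q_gain": 0.08, "chr4q_gain": 0.04,
        "chr5p_gain": 0.035, "chr5q_gain": 0.053,
        "chr7p_gain": 0.03, "chr7q_gain": 0.03,
        "chr21p_gain": 0.07, "chr21q_gain": 0.018,
        "IRF4_gain": 0.02,
        "chr10q_loss": 0.01, "chr19p_loss": 0.05, "chr19q_loss": 0.05,
        "CDKN2A_loss": 0.04, "B2M_loss": 0.03, "FAS_loss": 0.02,
        "PTEN_loss": 0.02, "RB1_loss": 0.02, "CD58_loss": 0.03,
        "CD28_gain": 0.03, "TET3": 0.10, "KMT2D": 0.12, "SOCS1": 0.08,
        "PIK3CD": 0.03, "STAT3": 0.08,
    },
    "C2": {
        "TET2": 0.51, "RHOA": 0.05, "IDH2": 0.01, "DNMT3A": 0.15,
        "TP53": 0.50, "CD28": 0.10, "PLCG1": 0.30, "VAV1": 0.10,
        "HLA-A": 0.30, "NFKBIZ_SV": 0.03,
        "chr1q_gain": 0.35, "chr4q_gain": 0.30,
        "chr5p_gain": 0.15, "chr5q_gain": 0.15,
        "chr7p_gain": 0.40, "chr7q_gain": 0.40,
        "chr21p_gain": 0.10, "chr21q_gain": 0.10,
        "IRF4_gain": 0.30,
        "chr10q_loss": 0.30, "chr19p_loss": 0.25, "chr19q_loss": 0.25,
        "CDKN2A_loss": 0.50, "B2M_loss": 0.25, "FAS_loss": 0.20,
        "PTEN_loss": 0.20, "RB1_loss": 0.20, "CD58_loss": 0.20,
        "CD28_gain": 0.25, "TET3": 0.05, "KMT2D": 0.15, "SOCS1": 0.12,
        "PIK3CD": 0.20, "STAT3": 0.10,
    },
    "C3": {
        "TET2": 0.83, "RHOA": 0.735, "IDH2": 0.676, "DNMT3A": 0.25,
        "TP53": 0.05, "CD28": 0.265, "PLCG1": 0.15, "VAV1": 0.10,
        "HLA-A": 0.08, "NFKBIZ_SV": 0.03,
        "chr1q_gain": 0.12, "chr4q_gain": 0.05,
        "chr5p_gain": 0.559, "chr5q_gain": 0.559,
        "chr7p_gain": 0.03, "chr7q_gain": 0.03,
        "chr21p_gain": 0.412, "chr21q_gain": 0.235,
        "IRF4_gain": 0.03,
        "chr10q_loss": 0.01, "chr19p_loss": 0.05, "chr19q_loss": 0.05,
        "CDKN2A_loss": 0.03, "B2M_loss": 0.03, "FAS_loss": 0.02,
        "PTEN_loss": 0.02, "RB1_loss": 0.02, "CD58_loss": 0.03,
        "CD28_gain": 0.05, "TET3": 0.10, "KMT2D": 0.10, "SOCS1": 0.08,
        "PIK3CD": 0.03, "STAT3": 0.08,
    },
    "C0": {},
}

#: the curated driver feature panel (34 features), i.e. the features that
#: enter the gene-sample matrix; background passenger arm CNAs do not.
DRIVER_PANEL = tuple(sorted(DEFAULT_DRIVER_FREQS["C1"]))

#: hallmark blocks whose alterations co-occur within a case beyond what the
#: subtype composition explains: the classical-TFH block (IDH2 mutations
#: with chromosome 5 / 21 arm gains and CD28/RHOA) and the chromosomal-
#: instability / tumor-suppressor block.  Within a block, a latent per-case
#: factor couples the draws (marginal frequencies are preserved exactly);
#: the coupling weight is ``SimulationConfig.coherence``.
COHERENCE_BLOCKS = {
    "classical_tfh": (
        "IDH2", "chr5p_gain", "chr5q_gain", "chr21p_gain", "chr21q_gain",
    ),
    "instability": (
        "TP53", "CDKN2A_loss", "chr1q_gain", "chr4q_gain", "chr7p_gain",
        "chr7q_gain", "chr10q_loss", "chr19p_loss", "chr19q_loss",
        "IRF4_gain", "RB1_loss", "PTEN_loss", "FAS_loss", "B2M_loss",
        "CD58_loss", "CD28_gain",
    ),
}

#: per-gene probability that an SNV is missense (remainder truncating).
#: RHOA (Gly17Val) and IDH2 (Arg172) are hotspot missense mutations; the TET2
#: value reproduces the observed double-mutant consequence spectrum
#: (~6.5/37/56.5% mis-mis/mis-trunc/trunc-trunc under independence).
MISSENSE_PROB = {
    "TET2": 0.25, "RHOA": 1.0, "IDH2": 1.0, "DNMT3A": 0.6, "TP53": 0.7,
    "CD28": 0.9, "PLCG1": 0.9, "VAV1": 0.8, "HLA-A": 0.5, "TET3": 0.3,
    "KMT2D": 0.3, "SOCS1": 0.4, "PIK3CD": 0.9, "STAT3": 0.9,
}

#: probability that a TET2-mutated case carries >=2 TET2 mutations, per
#: subtype; the overall rate lands near the reported 55/91.
TET2_MULTI_PROB = {"C0": 0.0, "C1": 0.55, "C2": 0.30, "C3": 0.75}
#: among multi-TET2 cases: probability of exactly two (else three) mutations
TET2_DOUBLE_GIVEN_MULTI = 0.85

#: pathology mixture per genetic subtype (case counts back-derived from the
#: printed cluster compositions: C1 84% nTFHL, C3 94% nTFHL, C2 32% nTFHL).
DEFAULT_PATHOLOGY_MIX = {
    "C1": {"AITL": 43 / 57, "nTFHL-other": 5 / 57, "PTCL-NOS": 9 / 57},
    "C2": {"AITL": 8 / 28, "nTFHL-other": 1 / 28, "PTCL-NOS": 19 / 28},
    "C3": {"AITL": 30 / 34, "nTFHL-other": 2 / 34, "PTCL-NOS": 2 / 34},
    "C0": {"AITL": 4 / 10, "nTFHL-other": 1 / 10, "PTCL-NOS": 5 / 10},
}

#: TME signature mixture per genetic subtype (C1/C2 printed; the remainder of
#: the 57-case expression cohort assigned to C3; C0 uniform).
DEFAULT_TME_MIX = {
    "C1": {"TME1": 3 / 26, "TME2": 2 / 26, "TME3": 21 / 26},
    "C2": {"TME1": 1 / 14, "TME2": 9 / 14, "TME3": 4 / 14},
    "C3": {"TME1": 9 / 17, "TME2": 5 / 17, "TME3": 3 / 17},
    "C0": {"TME1": 1 / 3, "TME2": 1 / 3, "TME3": 1 / 3},
}

#: overall TME mixture of the expression sub-cohort (13/16/28 of 57 cases);
#: used when simulating TME-labelled survival cohorts directly.
DEFAULT_TME_PROPORTIONS = {"TME1": 13 / 57, "TME2": 16 / 57, "TME3": 28 / 57}

# ---------------------------------------------------------------------------
# Chromosome arms.  The 11 recurrent arm-level CNAs enter DRIVER_FREQS above;
# the remaining autosomal arms receive pathology-level background rates
# calibrated so the median arm-level CNA count per case is 4 in PTCL-NOS and
# 1 in AITL.
# ---------------------------------------------------------------------------
AUTOSOME_ARMS = tuple(
    f"chr{c}{arm}" for c in range(1, 23) for arm in ("p", "q")
)
RECURRENT_ARM_FEATURES = (
    "chr1q_gain", "chr4q_gain", "chr5p_gain", "chr5q_gain",
    "chr7p_gain", "chr7q_gain", "chr21p_gain", "chr21q_gain",
    "chr10q_loss", "chr19p_loss", "chr19q_loss",
)
RECURRENT_ARMS = tuple(sorted({f.rsplit("_", 1)[0] for f in RECURRENT_ARM_FEATURES}))
BACKGROUND_ARMS = tuple(a for a in AUTOSOME_ARMS if a not in RECURRENT_ARMS)

#: per-arm background alteration probability by pathology (simulation-
#: calibrated to the printed medians; see docs/methods.md).
DEFAULT_ARM_CNA_RATES = {
    "AITL": 0.013,
    "nTFHL-other": 0.013,
    "PTCL-NOS": 0.066,
}

# ---------------------------------------------------------------------------
# Immune cell types (LM22-style) and TME mean fraction profiles.
# ---------------------------------------------------------------------------
CELL_TYPES = (
    "B_naive", "B_memory", "Plasma",
    "CD8_T", "CD4_naive", "CD4_memory_resting", "CD4_memory_activated",
    "TFH", "Treg", "gdT",
    "NK_resting", "NK_activated",
    "Monocyte", "Macrophage_M0", "Macrophage_M1", "Macrophage_M2",
    "DC_resting", "DC_activated",
    "Mast_resting", "Mast_activated",
    "Eosinophil", "Neutrophil",
)

TME1_MARKERS = ("B_naive", "B_memory", "TFH")
TME2_MARKERS = ("Macrophage_M0", "Macrophage_M1", "Macrophage_M2")
TME3_MARKERS = ("Mast_activated", "CD4_naive")


def default_tme_profiles() -> dict[str, dict[str, float]]:
    """Mean cell-type fraction vectors on the simplex for TME1/2/3.

    TME1 is enriched for naive/memory B and TFH cells, TME2 for macrophages
    plus activated-memory CD4 and CD8 T cells, TME3 for activated mast cells
    and naive CD4 T cells.
    """
    boosts = {
        "TME1": {"B_naive": 6.0, "B_memory": 6.0, "TFH": 6.0},
        "TME2": {
            "Macrophage_M0": 4.0, "Macrophage_M1": 4.0, "Macrophage_M2": 5.0,
            "CD4_memory_activated": 5.0, "CD8_T": 3.0,
        },
        "TME3": {"Mast_activated": 6.0, "CD4_naive": 6.0},
    }
    profiles = {}
    for tme, boost in boosts.items():
        w = {ct: boost.get(ct, 1.0) for ct in CELL_TYPES}
        total = sum(w.values())
        profiles[tme] = {ct: v / total for ct, v in w.items()}
    return profiles
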