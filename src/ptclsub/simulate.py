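"""Synthetic PTCL cohort generator.

Produces cohorts with the statistical structure the downstream subtyping
analysis assumes: genetic subtypes with subtype-specific driver alteration
frequencies, pathology-dependent arm-level CNA burden, exponential overall
survival with planted subtype (or TME) hazard ratios and independent
exponential censoring, TET2/RHOA variant-allele-frequency structure with
bone-marrow counterparts, and bulk expression as noisy mixtures of an
immune signature matrix.

All randomness flows through a single integer seed; identical configuration
plus seed reproduces every table bit-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import defaults as d


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class VAFModel:
    """Parameters for tumor / bone-marrow VAF draws.

    purity_range : tumor-cell fraction of the tumor sample (uniform draw).
    ch_clone_range : clonal-hematopoiesis clone fraction among non-tumor
        hematopoietic cells (uniform draw).
    subclone_range : tumor-subclone fraction for second-hit mutations.
    detection_floor : minimum VAF considered detectable.
    config_mixing : probabilities of the three TET2 configurations
        (tumor-restricted, CH-plus-second-hit, CH-only).
    """

    purity_range: tuple[float, float] = (0.2, 0.6)
    ch_clone_range: tuple[float, float] = (0.05, 0.5)
    subclone_range: tuple[float, float] = (0.3, 1.0)
    detection_floor: float = 0.02
    config_mixing: tuple[float, float, float] = (0.25, 0.375, 0.375)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the published cohort structure (129 cases split
    57/28/34/10 across C1/C2/C3/C0, subtype hazard ratios 2.52 and 2.14 for
    C2 and C3 versus C1, ~40% censoring, printed subtype-specific driver
    frequencies).
    """

    n_cases: int = d.DEFAULT_N_CASES
    subtype_proportions: dict[str, float] = field(
        default_factory=lambda: dict(d.DEFAULT_SUBTYPE_PROPORTIONS))
    driver_freqs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(f) for s, f in d.DEFAULT_DRIVER_FREQS.items()})
    arm_cna_rates: dict[str, float] = field(
        default_factory=lambda: dict(d.DEFAULT_ARM_CNA_RATES))
    pathology_mix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(m) for s, m in d.DEFAULT_PATHOLOGY_MIX.items()})
    tme_mix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(m) for s, m in d.DEFAULT_TME_MIX.items()})
    hazard_ratios: dict[str, float] = field(
        default_factory=lambda: dict(d.DEFAULT_HAZARD_RATIOS))
    tme_hazard_ratios: dict[str, float] = field(
        default_factory=lambda: dict(d.DEFAULT_TME_HAZARD_RATIOS))
    #: which planted label drives the event hazard: "subtype" or "tme"
    survival_on: str = "subtype"
    baseline_hazard: float = d.DEFAULT_BASELINE_HAZARD
    censor_rate: float = d.DEFAULT_CENSOR_RATE
    pretreatment_fraction: float = d.DEFAULT_PRETREATMENT_FRACTION
    tme_profiles: dict[str, dict[str, float]] = field(
        default_factory=d.default_tme_profiles)
    #: Dirichlet concentration for per-case fraction draws around the profile
    tme_concentration: float = 150.0
    #: per-block prevalence of the latent block-positive phenotype (the
    #: fraction of cases in which hallmark-block alterations concentrate);
    #: 1.0 disables the coupling.  Marginal driver frequencies are preserved
    #: exactly for any value.
    coherence: dict[str, float] = field(
        default_factory=lambda: {"classical_tfh": 0.75, "instability": 0.95})
    noise_sd: float = 0.1
    vaf_model: VAFModel = field(default_factory=VAFModel)
    tet2_multi_prob: dict[str, float] = field(
        default_factory=lambda: dict(d.TET2_MULTI_PROB))
    seed: int = 0

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.n_cases <= 0:
            raise ConfigurationError("n_cases must be positive")
        tot = sum(self.subtype_proportions.values())
        if abs(tot - 1.0) > 1e-9:
            raise ConfigurationError(
                f"subtype_proportions sum to {tot}, expected 1")
        for s, p in self.subtype_proportions.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"proportion for {s} outside [0,1]")
        for s in self.driver_freqs:
            if s not in self.subtype_proportions:
                raise ConfigurationError(f"unknown subtype key {s!r} in driver_freqs")
            for feat, p in self.driver_freqs[s].items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"driver frequency for ({s}, {feat}) outside [0,1]")
        ref_ok = any(v == 1.0 for v in self.hazard_ratios.values())
        if not ref_ok:
            raise ConfigurationError("hazard_ratios must contain a reference level 1.0")
        if any(v <= 0 for v in self.hazard_ratios.values()):
            raise ConfigurationError("hazard ratios must be positive")
        for tme, prof in self.tme_profiles.items():
            vals = np.asarray(list(prof.values()), dtype=float)
            if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"tme_profiles[{tme}] must be nonnegative and sum to 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        for blk, w in self.coherence.items():
            if not 0.0 < w <= 1.0:
                raise ConfigurationError(
                    f"coherence[{blk}] must lie in (0, 1]")
        if self.survival_on not in ("subtype", "tme"):
            raise ConfigurationError("survival_on must be 'subtype' or 'tme'")

    # -- (de)serialization -------------------------------------------------
    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["vaf_model"]["purity_range"] = list(self.vaf_model.purity_range)
        data["vaf_model"]["ch_clone_range"] = list(self.vaf_model.ch_clone_range)
        data["vaf_model"]["subclone_range"] = list(self.vaf_model.subclone_range)
        data["vaf_model"]["config_mixing"] = list(self.vaf_model.config_mixing)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        vm = data.pop("vaf_model", {})
        for k in ("purity_range", "ch_clone_range", "subclone_range", "config_mixing"):
            if k in vm:
                vm[k] = tuple(vm[k])
        cfg = cls(**data, vaf_model=VAFModel(**vm))
        return cfg


def _draw_categorical(rng, labels, probs, size):
    p = np.asarray(probs, dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(labels), size=size, p=p)
    return np.asarray(labels, dtype=object)[idx]


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort table and its driver alteration call table.

    Returns
    -------
    cohort : DataFrame with columns case_id, pathology, true_subtype,
        true_tme, pretreatment, time, event.
    calls : DataFrame with columns case_id, feature, alt_class, consequence,
        variant_id, vaf_tumor, vaf_bm (VAFs NaN until :func:`simulate_vafs`).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases

    subtypes = list(config.subtype_proportions)
    true_subtype = _draw_categorical(
        rng, subtypes, [config.subtype_proportions[s] for s in subtypes], n)

    case_id = np.array([f"T{1001 + i}" for i in range(n)], dtype=object)

    pathology = np.empty(n, dtype=object)
    true_tme = np.empty(n, dtype=object)
    for i, s in enumerate(true_subtype):
        pmix = config.pathology_mix[s]
        pathology[i] = _draw_categorical(rng, list(pmix), list(pmix.values()), 1)[0]
        tmix = config.tme_mix[s]
        true_tme[i] = _draw_categorical(rng, list(tmix), list(tmix.values()), 1)[0]

    # pretreatment flag: fixed expected fraction of cases sampled pre-therapy
    pretreatment = rng.random(n) < config.pretreatment_fraction

    # survival: exponential event time under the planted hazard, independent
    # exponential censoring
    label = true_subtype if config.survival_on == "subtype" else true_tme
    hrs = (config.hazard_ratios if config.survival_on == "subtype"
           else config.tme_hazard_ratios)
    haz = np.array([config.baseline_hazard * hrs[l] for l in label])
    t_event = rng.exponential(1.0 / haz)
    if config.censor_rate > 0:
        t_cens = rng.exponential(1.0 / config.censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens

    cohort = pd.DataFrame({
        "case_id": case_id,
        "pathology": pathology,
        "true_subtype": true_subtype,
        "true_tme": true_tme,
        "pretreatment": pretreatment,
        "time": time,
        "event": event,
    })

    calls = _simulate_calls(cohort, config, rng)
    return cohort, calls


def _simulate_calls(cohort, config, rng) -> pd.DataFrame:
    rows = []
    for _, case in cohort.iterrows():
        s = case.true_subtype
        freqs = config.driver_freqs.get(s, {})
        counter: dict[str, int] = {}

        def add(feature, alt_class, consequence, driver=True):
            k = counter.get(feature, 0) + 1
            counter[feature] = k
            rows.append({
                "case_id": case.case_id,
                "feature": feature,
                "alt_class": alt_class,
                "consequence": consequence,
                "variant_id": f"{feature}_{k}",
                "driver": driver,
                "vaf_tumor": np.nan,
                "vaf_bm": np.nan,
            })

        # latent per-case phenotype class per hallmark block: with
        # probability w = coherence[block] the case is block-positive and
        # carries block features at elevated rate p_hi = min(1, p/w),
        # otherwise at the reduced rate solving w*p_hi + (1-w)*p_lo = p, so
        # every marginal frequency is preserved exactly.  This couples
        # hallmark alterations within a case (classical-AITL and
        # chromosomal-instability phenotypes) without changing frequencies.
        block_state = {b: rng.random() < config.coherence.get(b, 1.0)
                       for b in d.COHERENCE_BLOCKS}
        block_of = {f: b for b, feats in d.COHERENCE_BLOCKS.items()
                    for f in feats}
        for feat, p in freqs.items():
            blk = block_of.get(feat)
            w = config.coherence.get(blk, 1.0) if blk else 1.0
            if blk is not None and w < 1.0:
                p_hi = min(1.0, p / w)
                p_lo = (p - w * p_hi) / (1.0 - w)
                p_eff = p_hi if block_state[blk] else p_lo
            else:
                p_eff = p
            if rng.random() >= p_eff:
                continue
            if feat.endswith("_gain"):
                add(feat, "CNA_gain", "NA")
            elif feat.endswith("_loss"):
                add(feat, "CNA_loss", "NA")
            elif feat.endswith("_SV"):
                add(feat, "SV", "other")
            else:
                n_mut = 1
                if feat == "TET2" and rng.random() < config.tet2_multi_prob.get(s, 0.0):
                    n_mut = 2 if rng.random() < d.TET2_DOUBLE_GIVEN_MULTI else 3
                pmis = d.MISSENSE_PROB.get(feat, 0.7)
                for _ in range(n_mut):
                    cons = "missense" if rng.random() < pmis else "truncating"
                    add(feat, "SNV", cons)

        # background arm-level CNAs on the non-recurrent arms
        rate = config.arm_cna_rates.get(case.pathology, 0.0)
        if rate > 0:
            hit = rng.random(len(d.BACKGROUND_ARMS)) < rate
            kinds = rng.random(len(d.BACKGROUND_ARMS)) < 0.5
            for arm, h, is_gain in zip(d.BACKGROUND_ARMS, hit, kinds):
                if h:
                    kind = "gain" if is_gain else "loss"
                    add(f"{arm}_{kind}", f"CNA_{kind}", "NA", driver=False)

    cols = ["case_id", "feature", "alt_class", "consequence",
            "variant_id", "driver", "vaf_tumor", "vaf_bm"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# VAF structure
# ---------------------------------------------------------------------------
TET2_CONFIGURATIONS = ("tumor_restricted", "ch_second_hit", "ch_only")


def simulate_vafs(cohort: pd.DataFrame, calls: pd.DataFrame,
                  config: SimulationConfig,
                  configuration: str | None = None) -> pd.DataFrame:
    """Fill tumor and bone-marrow VAFs on the call table.

    Each case draws a tumor purity; RHOA (and other non-TET2 SNVs) are
    heterozygous clonal tumor mutations with tumor VAF = purity/2.  Each
    TET2-mutated case is assigned one of three clonal configurations
    (optionally forced via ``configuration``):

    - ``tumor_restricted``: all TET2 mutations confined to tumor cells
      (bone-marrow VAF 0);
    - ``ch_second_hit``: one TET2 mutation derives from a clonal-
      hematopoiesis (CH) clone (detectable in bone marrow) and at least one
      second hit is tumor-restricted;
    - ``ch_only``: every TET2 mutation derives from CH clones.

    CH-derived mutations have tumor VAF (purity + (1-purity)*c)/2 where c is
    the CH clone fraction, and bone-marrow VAF c/2.
    """
    if configuration is not None and configuration not in TET2_CONFIGURATIONS:
        raise ValueError(f"unknown TET2 configuration {configuration!r}")
    vm = config.vaf_model
    rng = np.random.default_rng(config.seed + 104729)  # independent stream
    calls = calls.copy()

    purity = {cid: rng.uniform(*vm.purity_range) for cid in cohort.case_id}

    snv_mask = calls.alt_class == "SNV"
    for cid, idx in calls.index[snv_mask].to_series().groupby(
            calls.loc[snv_mask, "case_id"]).groups.items():
        pur = purity.get(cid)
        if pur is None:
            continue
        sub = calls.loc[idx]
        tet2_idx = sub.index[sub.feature == "TET2"]
        other_idx = sub.index.difference(tet2_idx)
        # non-TET2 SNVs: clonal heterozygous tumor mutations
        calls.loc[other_idx, "vaf_tumor"] = pur / 2.0
        calls.loc[other_idx, "vaf_bm"] = 0.0

        n_tet2 = len(tet2_idx)
        if n_tet2 == 0:
            continue
        pattern = configuration
        if pattern is None:
            probs = np.asarray(vm.config_mixing, dtype=float)
            probs = probs / probs.sum()
            pattern = TET2_CONFIGURATIONS[rng.choice(3, p=probs)]
        if pattern == "ch_second_hit" and n_tet2 < 2:
            pattern = "tumor_restricted"  # needs two hits

        if pattern == "tumor_restricted":
            calls.loc[tet2_idx, "vaf_tumor"] = pur / 2.0
            calls.loc[tet2_idx, "vaf_bm"] = 0.0
        elif pattern == "ch_only":
            for j in tet2_idx:
                c = rng.uniform(*vm.ch_clone_range)
                calls.loc[j, "vaf_tumor"] = (pur + (1 - pur) * c) / 2.0
                calls.loc[j, "vaf_bm"] = c / 2.0
        else:  # ch_second_hit: first mutation CH, the rest tumor-restricted
            c = rng.uniform(*vm.ch_clone_range)
            first = tet2_idx[0]
            calls.loc[first, "vaf_tumor"] = (pur + (1 - pur) * c) / 2.0
            calls.loc[first, "vaf_bm"] = c / 2.0
            for j in tet2_idx[1:]:
                sub_frac = rng.uniform(*vm.subclone_range)
                calls.loc[j, "vaf_tumor"] = pur * sub_frac / 2.0
                calls.loc[j, "vaf_bm"] = 0.0

    return calls


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------
def lm22_like_signature(seed: int = 0, markers_per_type: int = 9,
                        background: float = 0.3) -> pd.DataFrame:
    """Synthetic LM22-style signature matrix (genes x 22 cell types).

    Block-structured: each cell type owns ``markers_per_type`` marker genes
    with high expression (uniform 5-10) plus low off-target background and
    mild overlap noise.  This is a synthetic stand-in with the same shape and
    role as a real LM22 file, which can be substituted via configuration.
    """
    rng = np.random.default_rng(seed)
    n_types = len(d.CELL_TYPES)
    n_genes = n_types * markers_per_type
    genes = [f"SIG{g:04d}" for g in range(n_genes)]
    S = rng.uniform(0.0, background, size=(n_genes, n_types))
    for t in range(n_types):
        block = slice(t * markers_per_type, (t + 1) * markers_per_type)
        S[block, t] = rng.uniform(5.0, 10.0, size=markers_per_type)
        # mild cross-reactivity with one random other type
        other = rng.integers(0, n_types)
        if other != t:
            S[block, other] += rng.uniform(0.0, 1.0, size=markers_per_type)
    return pd.DataFrame(S, index=genes, columns=list(d.CELL_TYPES))


def simulate_expression(cohort: pd.DataFrame, signature: pd.DataFrame,
                        config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bulk expression as noisy signature mixtures.

    Per case, a cell-type fraction vector is drawn from a Dirichlet centred
    on the case's planted TME profile; the bulk column is signature x
    fractions plus truncated Gaussian noise (sd ``config.noise_sd``), clipped
    at zero.

    Returns ``(bulk, fractions)`` where ``bulk`` is genes x cases and
    ``fractions`` the planted cases x cell-type simplex matrix.
    """
    config.validate()
    cell_types = list(signature.columns)
    for tme, prof in config.tme_profiles.items():
        missing = set(prof) - set(cell_types)
        if missing:
            raise ConfigurationError(
                f"tme_profiles[{tme}] names cell types absent from the "
                f"signature: {sorted(missing)}")
    rng = np.random.default_rng(config.seed + 15485863)
    S = signature.to_numpy(dtype=float)
    cols = {}
    frac_rows = {}
    for _, case in cohort.iterrows():
        prof = config.tme_profiles[case.true_tme]
        alpha = np.array([prof.get(ct, 1e-6) for ct in cell_types]) \
            * config.tme_concentration
        f = rng.dirichlet(np.maximum(alpha, 1e-6))
        b = S @ f
        if config.noise_sd > 0:
            b = b + rng.normal(0.0, config.noise_sd, size=b.shape)
        cols[case.case_id] = np.clip(b, 0.0, None)
        frac_rows[case.case_id] = f
    bulk = pd.DataFrame(cols, index=signature.index)
    fractions = pd.DataFrame.from_dict(frac_rows, orient="index",
                                       columns=cell_types)
    return bulk, fractions


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------
def count_arm_cnas(calls: pd.DataFrame, case_ids=None) -> pd.Series:
    """Number of distinct arm-level CNA features per case.

    Counts features of the form ``chr<N><p|q>_(gain|loss)``; cases without
    any such event (including cases absent from the call table when
    ``case_ids`` is given) count zero.
    """
    arm = calls.feature.str.match(r"^chr\d+[pq]_(gain|loss)$")
    per_case = (calls[arm].groupby("case_id")["feature"].nunique())
    if case_ids is not None:
        per_case = per_case.reindex(case_ids, fill_value=0)
    return per_case.astype(int)
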