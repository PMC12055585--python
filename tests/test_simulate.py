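"""Synthetic-cohort generator: determinism, calibration, VAF structure."""

import numpy as np
import pandas as pd
import pytest

import ptclsub as p
from ptclsub.defaults import DEFAULT_DRIVER_FREQS
from ptclsub.simulate import ConfigurationError


def test_fixed_seed_reproduces_tables_exactly():
    cfg = p.SimulationConfig(seed=7)
    a_cohort, a_calls = p.simulate_cohort(cfg)
    b_cohort, b_calls = p.simulate_cohort(p.SimulationConfig(seed=7))
    pd.testing.assert_frame_equal(a_cohort, b_cohort)
    pd.testing.assert_frame_equal(a_calls, b_calls)
    va = p.simulate_vafs(a_cohort, a_calls, cfg)
    vb = p.simulate_vafs(b_cohort, b_calls, cfg)
    pd.testing.assert_frame_equal(va, vb)


def test_zero_driver_frequencies_give_empty_call_table():
    cfg = p.SimulationConfig(seed=1, driver_freqs={
        s: {f: 0.0 for f in fr} for s, fr in DEFAULT_DRIVER_FREQS.items()})
    cfg.arm_cna_rates = {k: 0.0 for k in cfg.arm_cna_rates}
    _, calls = p.simulate_cohort(cfg)
    assert len(calls) == 0


@pytest.mark.parametrize("bad", [
    dict(n_cases=0),
    dict(subtype_proportions={"C1": 0.6, "C2": 0.2}),
    dict(hazard_ratios={"C1": 2.0, "C2": 3.0, "C3": 2.0, "C0": 2.0}),
    dict(noise_sd=-0.1),
    dict(driver_freqs={"CX": {"TET2": 0.5}}),
])
def test_invalid_configurations_rejected(bad):
    with pytest.raises(ConfigurationError):
        p.SimulationConfig(seed=0, **bad).validate()


def test_planted_c2_log_hazard_matches_configuration():
    cfg = p.SimulationConfig()
    assert np.isclose(np.log(cfg.hazard_ratios["C2"]), np.log(2.52))
    assert cfg.hazard_ratios["C1"] == 1.0


def test_per_subtype_driver_frequencies_recovered_at_large_n():
    """Empirical per-subtype frequencies within +/-2% absolute at n=10,000
    (marginal preservation also under hallmark-block coupling); averaged
    over five cohorts so every feature-subtype pair is well-powered."""
    emps = []
    for seed in range(3, 8):
        cfg = p.SimulationConfig(n_cases=10000, seed=seed)
        cohort, calls = p.simulate_cohort(cfg)
        seen = (calls[calls.driver].groupby(["case_id", "feature"]).size() > 0)
        seen = seen.unstack(fill_value=False)
        by_case = seen.reindex(cohort.case_id, fill_value=False)
        by_case["subtype"] = cohort.true_subtype.to_numpy()
        emps.append(by_case.groupby("subtype").mean())
    emp = sum(emps) / len(emps)
    for s in ("C1", "C2", "C3"):
        for feat, want in DEFAULT_DRIVER_FREQS[s].items():
            got = emp.loc[s, feat] if feat in emp.columns else 0.0
            assert abs(got - want) < 0.02, (s, feat, got, want)


def test_arm_level_cna_burden_matches_pathology_medians():
    """Median arm-level CNA count per case: 4 in PTCL-NOS, 1 in AITL."""
    cfg = p.SimulationConfig(n_cases=10000, seed=11)
    cohort, calls = p.simulate_cohort(cfg)
    counts = p.count_arm_cnas(calls, case_ids=cohort.case_id)
    med = cohort.set_index("case_id").join(counts.rename("n")) \
        .groupby("pathology")["n"].median()
    assert med["PTCL-NOS"] == 4
    assert med["AITL"] == 1


def test_event_rate_ratio_converges_to_planted_hazard_ratio():
    """With no censoring, events/exposure ratios estimate the planted HRs."""
    cfg = p.SimulationConfig(n_cases=20000, seed=5, censor_rate=0.0)
    cohort, _ = p.simulate_cohort(cfg)
    assert cohort.event.all()
    g = cohort.groupby("true_subtype").apply(
        lambda d: d.event.sum() / d.time.sum(), include_groups=False)
    assert np.isclose(g["C2"] / g["C1"], 2.52, rtol=0.1)
    assert np.isclose(g["C3"] / g["C1"], 2.14, rtol=0.1)


def test_censoring_fraction_near_forty_percent():
    cfg = p.SimulationConfig(n_cases=20000, seed=6)
    cohort, _ = p.simulate_cohort(cfg)
    assert 0.3 < 1 - cohort.event.mean() < 0.5


# -- VAF structure ---------------------------------------------------------
def test_tumor_restricted_configuration_has_zero_bm_vafs(default_cohort):
    cfg, cohort, calls = default_cohort
    forced = p.simulate_vafs(cohort, calls, cfg,
                             configuration="tumor_restricted")
    tet2 = forced[(forced.feature == "TET2") & (forced.alt_class == "SNV")]
    assert len(tet2) > 0
    assert (tet2.vaf_bm == 0).all()


def test_ch_second_hit_has_bm_present_and_absent_mutations(default_cohort):
    cfg, cohort, calls = default_cohort
    forced = p.simulate_vafs(cohort, calls, cfg,
                             configuration="ch_second_hit")
    tet2 = forced[(forced.feature == "TET2") & (forced.alt_class == "SNV")]
    floor = cfg.vaf_model.detection_floor
    multi = tet2.groupby("case_id").filter(lambda g: len(g) >= 2)
    assert len(multi) > 0
    for _, grp in multi.groupby("case_id"):
        assert (grp.vaf_bm >= floor).any()
        assert (grp.vaf_bm == 0).any()


def test_pure_tumor_single_clone_gives_unit_vaf_ratio():
    """At purity 1 with a single tumor clone, TET2 and RHOA VAFs agree."""
    cfg = p.SimulationConfig(seed=2)
    cfg.vaf_model = p.VAFModel(purity_range=(1.0, 1.0))
    cohort, calls = p.simulate_cohort(cfg)
    filled = p.simulate_vafs(cohort, calls, cfg,
                             configuration="tumor_restricted")
    cc = p.clonal_calls(filled)
    ratios = cc.dropna(subset=["vaf_ratio"]).vaf_ratio
    assert len(ratios) > 0
    assert np.allclose(ratios, 1.0)


def test_vaf_ratio_invariant_to_common_purity_scaling(default_cohort):
    cfg, cohort, calls = default_cohort
    cc = p.clonal_calls(calls)
    scaled = calls.copy()
    scaled["vaf_tumor"] = scaled["vaf_tumor"] * 0.5
    cc2 = p.clonal_calls(scaled)
    ok = cc.dropna(subset=["vaf_ratio"])
    ok2 = cc2.dropna(subset=["vaf_ratio"])
    assert np.allclose(ok.vaf_ratio.to_numpy(), ok2.vaf_ratio.to_numpy())


# -- expression ------------------------------------------------------------
def test_noiseless_bulk_lies_in_signature_cone(signature):
    cfg = p.SimulationConfig(seed=4, n_cases=20, noise_sd=0.0)
    cohort, _ = p.simulate_cohort(cfg)
    bulk, planted = p.simulate_expression(cohort, signature, cfg)
    recon = signature.to_numpy() @ planted.T.to_numpy()
    assert np.allclose(bulk.to_numpy(), recon, atol=1e-10)


def test_macrophage_fraction_highest_in_tme2_b_tfh_in_tme1(signature):
    cfg = p.SimulationConfig(seed=4, n_cases=300)
    cohort, _ = p.simulate_cohort(cfg)
    _, planted = p.simulate_expression(cohort, signature, cfg)
    planted["tme"] = cohort.set_index("case_id").true_tme
    means = planted.groupby("tme").mean()
    mac = means[["Macrophage_M0", "Macrophage_M1", "Macrophage_M2"]].sum(1)
    assert mac.idxmax() == "TME2"
    btfh = means[["B_naive", "B_memory", "TFH"]].sum(1)
    assert btfh.idxmax() == "TME1"


def test_cell_type_mismatch_raises(signature):
    cfg = p.SimulationConfig(seed=0, n_cases=5)
    cfg.tme_profiles = {t: {"NotACell": 1.0} for t in cfg.tme_profiles}
    cohort, _ = p.simulate_cohort(p.SimulationConfig(seed=0, n_cases=5))
    with pytest.raises(ConfigurationError, match="NotACell"):
        p.simulate_expression(cohort, signature, cfg)


def test_config_yaml_round_trip(tmp_path):
    cfg = p.SimulationConfig(seed=42, n_cases=50)
    path = tmp_path / "sim.yaml"
    cfg.to_yaml(path)
    back = p.SimulationConfig.from_yaml(path)
    assert back == cfg
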