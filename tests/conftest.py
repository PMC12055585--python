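import numpy as np
import pandas as pd
import pytest

import ptclsub as p


@pytest.fixture(scope="session")
def default_cohort():
    """One default 129-case synthetic cohort with VAFs filled."""
    cfg = p.SimulationConfig(seed=7)
    cohort, calls = p.simulate_cohort(cfg)
    calls = p.simulate_vafs(cohort, calls, cfg)
    return cfg, cohort, calls


@pytest.fixture(scope="session")
def signature():
    return p.lm22_like_signature(seed=0)


def tet2_pair_calls():
    """Call table reproducing the published 46-pair double-TET2 consequence
    spectrum: 3 missense-missense, 17 missense-truncating and 26
    truncating-truncating cases."""
    rows = []
    spec = [("missense", "missense", 3), ("missense", "truncating", 17),
            ("truncating", "truncating", 26)]
    i = 0
    for c1, c2, n in spec:
        for _ in range(n):
            cid = f"P{i:03d}"
            i += 1
            for j, cons in enumerate((c1, c2), start=1):
                rows.append({"case_id": cid, "feature": "TET2",
                             "alt_class": "SNV", "consequence": cons,
                             "variant_id": f"TET2_{j}",
                             "vaf_tumor": np.nan, "vaf_bm": np.nan})
    return pd.DataFrame(rows)


@pytest.fixture
def tet2_pairs():
    return tet2_pair_calls()
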