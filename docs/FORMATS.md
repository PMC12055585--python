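# File formats

All inter-stage files are tab-separated text with a header row. Paths
below are the names written by `subtype all` / `run_pipeline`.

## cohort.tsv
One row per case.

| column | type | notes |
|---|---|---|
| case_id | string | unique |
| pathology | enum | AITL, nTFHL-other, PTCL-NOS |
| true_subtype | enum | C0..C3; planted truth (synthetic cohorts only) |
| true_tme | enum | TME1..TME3; planted truth (synthetic only) |
| pretreatment | bool | sample taken before therapy; survival fits use only these |
| time | float | overall survival, months |
| event | bool | death observed (False = censored) |

## calls.tsv
Long-format alteration calls, one row per event.

| column | type | notes |
|---|---|---|
| case_id | string | |
| feature | string | gene symbol, arm feature (`chr5p_gain`) or SV (`NFKBIZ_SV`) |
| alt_class | enum | SNV, SV, CNA_gain, CNA_loss |
| consequence | enum | missense, truncating, other, NA |
| variant_id | string | disambiguates multiple events per gene per case |
| driver | bool | False marks background (passenger) arm CNAs; these are excluded from the clustered matrix |
| vaf_tumor | float/NA | tumor variant allele frequency in [0,1] |
| vaf_bm | float/NA | bone-marrow VAF; >0 only for CH-derived mutations |

MAF input is also accepted by `ptclsub.features.read_maf`
(`Variant_Classification` → consequence: Missense_Mutation → missense;
Nonsense/Frame_Shift_*/Splice_Site/Nonstop → truncating; else other).

## driver_matrix.tsv
Binary matrix, features in rows (`feature` index column), cases in
columns; entries 0/1.

## rank_selection.tsv
`rank`, `cophenetic`, `selected` — one row per candidate rank.

## assignments.tsv / tme_labels.tsv
`case_id` plus `subtype` (C0..Ck) or `tme` (TME1..TMEk).

## consensus_selected.tsv / consensus_rank<k>.tsv
Symmetric cases × cases consensus matrix in [0,1], diagonal 1.

## associations.tsv
`feature_a, feature_b, a, b, c, d, odds_ratio, p, q, direction` where
a = both altered, b = a only, c = b only, d = neither; direction is
`co-occurrent` (OR ≥ 1) or `exclusive` (OR < 1); q is BH-adjusted over
the full screen.

## clonal_calls.tsv
`case_id, pattern, tet2_vaf_tumor_max, rhoa_vaf_tumor, vaf_ratio,
ratio_group` with pattern ∈ {tumor_restricted, ch_second_hit, ch_only,
unclassifiable} and ratio_group ∈ {high, low, NA}.

## bulk.tsv / signature.tsv
Genes in rows (first column `gene`), samples / cell types in columns;
nonnegative expression values.

## fractions.tsv
Cases × cell types; rows on the simplex (nonnegative, sum 1).

## survival_*.tsv / vaf_ratio_survival.tsv
`term, reference, n, events, hr, ci_low, ci_high, p` (+ `q` for the
univariate screen); one row per non-reference level.

## km_*.tsv
`group, time, survival, n_risk, n_event` — tidy product-limit curves.

## oncoprint.tsv
The driver matrix plus a `__subtype__` row giving each case's assigned
cluster — convenient for oncoprint-style plotting.

## manifest.json
Package version, seed, config hash, completed stages, output list and
skip notices. Contains no timestamps, so identical configurations yield
byte-identical output trees.

## Run configuration (YAML)
`RunConfig.to_yaml` / `from_yaml` round-trip the full configuration,
including the embedded simulation block and every stage seed.
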