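# ptclsub

Genetic subtyping and tumor-microenvironment (TME) signature analysis for
peripheral T-cell lymphoma (PTCL) cohorts.

Nodal TFH lymphoma (nTFHL, chiefly angioimmunoblastic T-cell lymphoma,
AITL) and PTCL-NOS are clinically heterogeneous. Integrating driver events
— single-nucleotide variants, structural variants, focal and arm-level copy
number alterations — into a binary gene-sample matrix and clustering it
reveals discrete genetic subtypes with different outcomes, and deconvolving
bulk expression into immune cell fractions reveals TME signature groups
that correlate with them. `ptclsub` implements that analysis stack as a
tested Python library plus a `subtype` command line, and ships a synthetic
cohort generator so every stage can be exercised end to end without access
to restricted patient data.

## What it computes

- **Driver matrix** — binary features × cases matrix from a long-format
  alteration call table, with a recurrence filter (features altered in ≥ 5
  cases) and a driver-negative "cluster 0" rule for cases left without any
  recurrent alteration.
- **NMF consensus subtyping** — Brunet-style nonnegative matrix
  factorization minimizing the Kullback–Leibler divergence
  D(V‖WH) = Σ V log(V/WH) − V + WH by multiplicative updates; 30 restarts
  per candidate rank k ∈ {2..8}; consensus matrix of co-assignment
  frequencies; rank selected by maximizing the cophenetic correlation of
  the consensus dissimilarities; subtypes C1..Ck (by descending size) from
  an average-linkage cut.
- **Exclusivity / co-occurrence** — two-sided Fisher exact tests over all
  feature pairs with Benjamini–Hochberg q values; single and multiple TET2
  mutations enter as separate features.
- **Clonal structure** — classification of TET2 mutation configurations
  from tumor vs bone-marrow VAFs (tumor-restricted / CH-plus-second-hit /
  CH-only, where CH is clonal hematopoiesis) and the TET2/RHOA VAF-ratio
  statistic with a median-split survival contrast.
- **TME signatures** — nonnegative-least-squares deconvolution of bulk
  expression against an LM22-style signature matrix, followed by
  hierarchical clustering (z-scored fractions, Euclidean, complete linkage)
  into TME1 (B/TFH-rich), TME2 (macrophage-rich), TME3 (mast-cell /
  naive-T-rich).
- **Survival** — Cox proportional-hazards contrasts (Efron ties, Wald CIs)
  and Kaplan–Meier summaries for subtypes, TME groups, VAF-ratio groups and
  single alterations.
- **Synthetic cohorts** — `SimulationConfig` defaults encode the published
  cohort structure: 129 cases split 57/28/34/10 across C1/C2/C3/C0,
  subtype-specific driver frequencies, arm-level CNA burden by pathology
  (median 4 per PTCL-NOS case vs 1 per AITL case), planted overall-survival
  hazard ratios (C2 2.52 and C3 2.14 vs C1; TME2 3.4 vs TME3), ~40%
  censoring, and TET2/RHOA VAF structure with bone-marrow counterparts.

## Worked example

```python
import ptclsub as p

cfg = p.SimulationConfig(seed=1)          # default 129-case cohort
cohort, calls = p.simulate_cohort(cfg)
calls = p.simulate_vafs(cohort, calls, cfg)

dm = p.build_driver_matrix(calls[calls.driver], case_ids=list(cohort.case_id))
res = p.ConsensusNMF(dm, seed=1).fit()
print(res)

surv = cohort[cohort.pretreatment].merge(
    res.assignments.rename("subtype"), left_on="case_id", right_index=True)
surv = surv[surv.subtype.isin(["C1", "C2", "C3"])]
print(p.cox_fit(surv.time, surv.event, surv.subtype, reference="C1").round(3))
```

prints

```
Consensus NMF subtyping
  selected rank: 2 (runs per rank: 30)
  cluster sizes: C0=9, C1=73, C2=47
  term reference   n  events     hr  ci_low  ci_high      p
0   C2        C1  41      29  1.795    1.09    2.954  0.021
```

Nine cases carry no recurrent driver and land in C0; the consensus
clustering of this replicate stabilizes at two genetic clusters, and the
smaller, tumor-suppressor/aneuploidy-driven cluster has roughly 1.8-fold
higher death hazard than the TFH-mutation-driven one (95% CI 1.09–2.95).
Fitting Cox on the *planted* labels instead recovers the configured hazard
ratios (see below).

The same stages are available from the shell:

```sh
subtype simulate --seed 1 -o run/
subtype matrix run/calls.tsv -o run/matrix.tsv
subtype nmf run/matrix.tsv --ranks 2:8 --runs 30 --seed 1 -o run/
subtype assoc run/matrix.tsv --tet2-split run/calls.tsv -o run/assoc.tsv
subtype tme run/bulk.tsv --signature run/signature.tsv -k 3 -o run/
subtype all -o run/            # full pipeline with a manifest
```

File formats are documented in `docs/FORMATS.md`.

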