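"""End-to-end pipeline orchestration.

Runs simulate -> driver matrix -> NMF subtyping -> association screen ->
clonal calls -> TME deconvolution/clustering -> survival contrasts from a
single YAML-serializable configuration, writing plain TSV outputs and a run
manifest.  Stages are also independently invocable through the CLI.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import pairwise_screen
from .clonal import vaf_ratio_split
from .features import build_driver_matrix, split_tet2_multiplicity
from .nmf import ConsensusNMF
from .simulate import (SimulationConfig, lm22_like_signature, simulate_cohort,
                       simulate_expression, simulate_vafs)
from .survival import cox_fit, km_curve
from .tme import cluster_tme, crosstab_subtypes, deconvolve

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Whole-pipeline configuration.

    Either the simulation block is used (default) or paths to existing
    input tables are supplied.  All module parameters carry explicit
    defaults and every random stage takes its seed from here.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    #: optional pre-existing inputs; when set, simulation is skipped
    cohort_path: str | None = None
    calls_path: str | None = None
    bulk_path: str | None = None
    signature_path: str | None = None
    #: stage parameters
    min_cases: int = 5
    ranks: tuple[int, int] = (2, 8)
    n_runs: int = 30
    k_tme: int = 3
    vaf_cutoff: str | float = "median"
    simulate_expression: bool = True
    seed: int = 0

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(_listify(data), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim = data.pop("simulation", {})
        from .simulate import VAFModel
        vm = sim.pop("vaf_model", {}) if isinstance(sim, dict) else {}
        for k in ("purity_range", "ch_clone_range", "subclone_range",
                  "config_mixing"):
            if k in vm:
                vm[k] = tuple(vm[k])
        simulation = SimulationConfig(**sim, vaf_model=VAFModel(**vm))
        if "ranks" in data:
            data["ranks"] = tuple(data["ranks"])
        return cls(simulation=simulation, **data)


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, list):
        return [_listify(v) for v in obj]
    return obj


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(_listify(dataclasses.asdict(config)),
                         sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages in dependency order; returns the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "ptclsub",
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": [],
        "outputs": [],
        "notices": [],
    }

    def emit(name: str, df: pd.DataFrame, index=False, index_label=None):
        path = out / name
        df.to_csv(path, sep="\t", index=index, index_label=index_label)
        manifest["outputs"].append(name)

    # -- simulate / load ---------------------------------------------------
    try:
        if config.cohort_path and config.calls_path:
            cohort = pd.read_csv(config.cohort_path, sep="\t")
            calls = pd.read_csv(config.calls_path, sep="\t")
        else:
            sim = config.simulation
            cohort, calls = simulate_cohort(sim)
            calls = simulate_vafs(cohort, calls, sim)
        emit("cohort.tsv", cohort)
        emit("calls.tsv", calls)
        manifest["stages"].append("simulate")
    except Exception as exc:
        raise StageError("simulate", str(exc)) from exc

    # -- driver matrix -----------------------------------------------------
    # passenger events (driver == False) model background CNA burden and are
    # excluded from subtyping, mirroring the upstream driver curation of the
    # published workflow
    try:
        driver_calls = calls[calls.driver] if "driver" in calls.columns else calls
        dm = build_driver_matrix(driver_calls, min_cases=config.min_cases,
                                 case_ids=list(cohort.case_id))
        dm.to_tsv(out / "driver_matrix.tsv")
        manifest["outputs"].append("driver_matrix.tsv")
        manifest["stages"].append("matrix")
    except Exception as exc:
        raise StageError("matrix", str(exc)) from exc

    # -- NMF subtyping -----------------------------------------------------
    try:
        lo, hi = config.ranks
        res = ConsensusNMF(dm, ranks=range(lo, hi + 1), n_runs=config.n_runs,
                           seed=config.seed).fit()
        emit("rank_selection.tsv", res.summary())
        assignments = res.assignments.rename("subtype").rename_axis("case_id")
        emit("assignments.tsv", assignments.reset_index())
        emit("consensus_selected.tsv", res.consensus(), index=True,
             index_label="case_id")
        # oncoprint-style panel: features x cases with subtype header row
        onco = dm.values.copy()
        onco.loc["__subtype__"] = [assignments.get(c, "C0")
                                   for c in onco.columns]
        emit("oncoprint.tsv", onco, index=True, index_label="feature")
        manifest["stages"].append("nmf")
        manifest["selected_rank"] = res.selected_rank
    except Exception as exc:
        raise StageError("nmf", str(exc)) from exc

    # -- association screen ------------------------------------------------
    try:
        tet2_split = split_tet2_multiplicity(calls)
        assoc = pairwise_screen(dm.values, tet2_split=tet2_split)
        emit("associations.tsv", assoc)
        manifest["stages"].append("assoc")
    except Exception as exc:
        raise StageError("assoc", str(exc)) from exc

    # -- clonal structure --------------------------------------------------
    try:
        clonal_tab, ratio_fit = vaf_ratio_split(
            calls, cohort[["case_id", "time", "event"]],
            cutoff=config.vaf_cutoff)
        emit("clonal_calls.tsv", clonal_tab)
        if ratio_fit is not None:
            emit("vaf_ratio_survival.tsv", ratio_fit)
        manifest["stages"].append("clonal")
    except Exception as exc:
        raise StageError("clonal", str(exc)) from exc

    # -- TME ---------------------------------------------------------------
    tme_labels = None
    try:
        if config.bulk_path and config.signature_path:
            bulk = pd.read_csv(config.bulk_path, sep="\t", index_col=0)
            signature = pd.read_csv(config.signature_path, sep="\t",
                                    index_col=0)
        elif config.simulate_expression and not config.cohort_path:
            signature = lm22_like_signature(seed=config.seed)
            bulk, _ = simulate_expression(cohort, signature, config.simulation)
        else:
            bulk = signature = None
            manifest["notices"].append(
                "TME stage skipped: no expression inputs configured")
        if bulk is not None:
            fractions = deconvolve(bulk, signature)
            emit("fractions.tsv", fractions, index=True,
                 index_label="case_id")
            tme_labels = cluster_tme(fractions, k=config.k_tme)
            emit("tme_labels.tsv", tme_labels.rename_axis("case_id")
                 .reset_index())
            table, fisher = crosstab_subtypes(assignments, tme_labels)
            emit("subtype_tme_crosstab.tsv", table, index=True,
                 index_label="subtype")
            emit("subtype_tme_fisher.tsv", fisher)
            manifest["stages"].append("tme")
    except Exception as exc:
        raise StageError("tme", str(exc)) from exc

    # -- survival ----------------------------------------------------------
    try:
        surv = cohort[cohort.pretreatment].merge(
            assignments.rename("subtype"), left_on="case_id",
            right_index=True, how="left")
        surv = surv[surv.subtype.isin(["C1", "C2", "C3"])]
        fits = cox_fit(surv.time, surv.event, surv.subtype, reference="C1")
        emit("survival_subtypes.tsv", fits)
        emit("km_subtypes.tsv", km_curve(surv.time, surv.event, surv.subtype))
        if tme_labels is not None:
            tsurv = cohort[cohort.pretreatment].merge(
                tme_labels.rename("tme"), left_on="case_id",
                right_index=True, how="inner")
            try:
                tfits = cox_fit(tsurv.time, tsurv.event, tsurv.tme,
                                reference="TME3")
                emit("survival_tme.tsv", tfits)
            except ValueError as exc:
                manifest["notices"].append(f"TME survival skipped: {exc}")
        manifest["stages"].append("surv")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("surv", str(exc)) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
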