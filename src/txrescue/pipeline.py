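"""End-to-end pipeline driver.

Chains QC -> log-normalization -> {single-cell rank-sum DE, pseudo-bulk
moderated DE} -> paired bulk DE -> cross-species integration (rescue
fractions, conserved sets, exclusive intersections) -> per-condition
cell-cell communication -> over-representation analysis -> cell-type
composition, recording a provenance log (config hash, seed, library
versions, per-stage sizes) sufficient to re-execute the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .simdata import CohortConfig, SyntheticCohort, generate_cohort
from .qc import QCThresholds, QCReport, apply_qc
from .diffexpr import (DesignSpec, SignificanceProfile, PROFILES, classify,
                       de_paired_bulk, de_wilcoxon, filter_low_expression,
                       fit_moderated, lognormalize, precision_weighted_transform,
                       pseudobulk, tmm_factors)
from .integration import IntegrationResult, integrate, upset_counts
from .communication import (CommParams, CommunicationTensor, aggregate_network,
                            network_centrality, permutation_significance)
from .enrichment import GeneSetCollection, composition, ora_hypergeometric
from . import io as txio

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs; all randomness flows from ``seed``."""

    cohort: CohortConfig | None = None        # generate inputs when set
    input_dir: str | None = None              # ... or load them from disk
    qc: QCThresholds = field(default_factory=QCThresholds)
    profiles: dict[str, SignificanceProfile] = field(
        default_factory=lambda: dict(PROFILES))
    comm: CommParams = field(default_factory=CommParams)
    protein_coding_only: bool = True
    responsive_analyses: tuple[str, ...] | None = None   # default: union of both mouse tables
    run_communication: bool = True
    gene_sets: GeneSetCollection | None = None
    seed: int = 0

    def validate(self) -> None:
        if (self.cohort is None) == (self.input_dir is None):
            raise ValueError("exactly one of cohort / input_dir must be set")
        for key in ("snrna", "pseudobulk", "human", "population"):
            if key not in self.profiles:
                raise ValueError(f"profiles is missing the {key!r} entry")

    def hash(self) -> str:
        def _enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {k: _enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, dict):
                return {k: _enc(v) for k, v in sorted(o.items())}
            if isinstance(o, (list, tuple, frozenset, set)):
                return [_enc(v) for v in o]
            if isinstance(o, float) and np.isinf(o):
                return "inf"
            if isinstance(o, GeneSetCollection):
                return {k: sorted(v) for k, v in o.sets.items()}
            return o
        blob = json.dumps(_enc(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class PipelineResult:
    qc_report: QCReport
    de_tables: dict[str, pd.DataFrame]
    directions: dict[str, pd.DataFrame]
    rescue_mouse: tuple[int, int, float | None]
    rescue_human: tuple[int, int, float | None]
    integration: IntegrationResult
    upset: pd.DataFrame
    communication: dict[str, CommunicationTensor]
    networks: dict[str, tuple[pd.DataFrame, pd.DataFrame, pd.Series]]
    centrality: dict[str, pd.DataFrame]
    enrichment: pd.DataFrame | None
    composition_per_sample: pd.DataFrame
    composition_pooled: pd.DataFrame
    provenance: dict


def _load_inputs(config: PipelineConfig) -> SyntheticCohort:
    if config.cohort is not None:
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
        return generate_cohort(cohort_cfg)
    d = Path(config.input_dir)
    snrna = txio.read_counts_10x(d / "snrna")
    bulk, meta = txio.read_bulk_tsv(d / "bulk_counts.tsv", d / "bulk_metadata.tsv")
    signature = txio.read_direction_table(d / "cancer_signature.tsv")
    orthologs = pd.read_csv(d / "ortholog_map.tsv", sep="\t")
    lr_table = pd.read_csv(d / "lr_pairs.tsv", sep="\t")
    return SyntheticCohort(snrna=snrna, bulk_counts=bulk, bulk_meta=meta,
                           cancer_signature=signature, ortholog_map=orthologs,
                           lr_table=lr_table, truth=None)


def _default_gene_sets(cohort: SyntheticCohort,
                       universe: list[str]) -> GeneSetCollection | None:
    """Gene sets seeded from the planted truth (synthetic runs only)."""
    if cohort.truth is None:
        return None
    h2m = dict(zip(cohort.truth.ortholog_map["gene_human"],
                   cohort.truth.ortholog_map["gene_mouse"]))
    planted = frozenset(h2m[g] for g in cohort.truth.treatment_direction_mouse
                        if g in h2m)
    rng = np.random.default_rng(0)
    sets = {"planted_treatment_program": planted & frozenset(universe)}
    pool = sorted(set(universe) - planted)
    for i in range(4):
        size = min(len(planted), len(pool))
        if size:
            sets[f"random_program_{i}"] = frozenset(
                rng.choice(pool, size=size, replace=False))
    return GeneSetCollection(sets=sets)


def run_pipeline(config: PipelineConfig,
                 outdir: str | None = None) -> PipelineResult:
    """Execute the full chain; any stage failure aborts naming the stage."""
    config.validate()
    provenance: dict = {
        "config_hash": config.hash(), "seed": config.seed,
        "versions": {"txrescue": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "stages": {},
    }
    stage = "load_inputs"
    try:
        cohort = _load_inputs(config)
        provenance["stages"][stage] = {
            "cells": int(cohort.snrna.n_obs), "genes": int(cohort.snrna.n_vars),
            "bulk_samples": int(cohort.bulk_counts.shape[1])}

        stage = "qc"
        filtered, qc_report = apply_qc(cohort.snrna, config.qc)
        provenance["stages"][stage] = qc_report.to_dict()

        stage = "lognormalize"
        norm = lognormalize(filtered)

        stage = "de_wilcoxon"
        sn_table = de_wilcoxon(norm, "treated", "control",
                               profile=config.profiles["snrna"],
                               groupby="condition")
        provenance["stages"][stage] = {
            "tested": int(sn_table["p_raw"].notna().sum())}

        stage = "de_pseudobulk"
        pb = pseudobulk(norm, sample_key="sample")
        cond_by_sample = (norm.obs.groupby("sample", observed=True)["condition"]
                          .first().loc[pb.columns])
        design = DesignSpec(condition=tuple(cond_by_sample))
        pb_f = filter_low_expression(pb, design)
        factors = tmm_factors(pb_f)
        logcpm, weights = precision_weighted_transform(pb_f, factors, design)
        pb_table = fit_moderated(logcpm, weights, design,
                                 profile=config.profiles["pseudobulk"])
        provenance["stages"][stage] = {"genes_kept": int(pb_f.shape[0])}

        stage = "de_paired_bulk"
        meta = cohort.bulk_meta.loc[cohort.bulk_counts.columns]
        hs_table = de_paired_bulk(cohort.bulk_counts, meta["patient"],
                                  meta["treatment"],
                                  profile=config.profiles["human"])
        provenance["stages"][stage] = {"genes_kept": int(hs_table.shape[0])}

        stage = "classify"
        directions = {
            "snrna": classify(sn_table, config.profiles["snrna"]),
            "pseudobulk": classify(pb_table, config.profiles["pseudobulk"]),
            "human": classify(hs_table, config.profiles["human"]),
            "cancer": cohort.cancer_signature[["gene", "direction"]].copy(),
        }

        stage = "integration"
        mouse_tables = {"snrna": directions["snrna"],
                        "pseudobulk": directions["pseudobulk"]}
        res_mouse = integrate(directions["cancer"], mouse_tables,
                              cohort.ortholog_map,
                              species_b=("snrna", "pseudobulk"),
                              protein_coding_only=False,
                              responsive_analyses=config.responsive_analyses)
        res_human = integrate(directions["cancer"],
                              {"human": directions["human"]},
                              cohort.ortholog_map, species_b=(),
                              protein_coding_only=False)
        result = integrate(directions["cancer"],
                           {**mouse_tables, "human": directions["human"]},
                           cohort.ortholog_map,
                           species_b=("snrna", "pseudobulk"),
                           protein_coding_only=config.protein_coding_only)
        n_resp_m = len(res_mouse.responsive)
        rescue_mouse = (n_resp_m, len(res_mouse.reversed_genes),
                        res_mouse.rescue_fraction)
        rescue_human = (len(res_human.responsive), len(res_human.reversed_genes),
                        res_human.rescue_fraction)
        joined = result.directions
        upset = upset_counts({
            "cancer_up": set(joined.index[joined["cancer"] == "up"]),
            "snrna_down": set(joined.index[joined["snrna"] == "down"]),
            "pseudobulk_down": set(joined.index[joined["pseudobulk"] == "down"]),
            "human_down": set(joined.index[joined["human"] == "down"]),
        })
        provenance["stages"][stage] = {
            "universe": len(result.shared_universe),
            "conserved_down": sorted(result.conserved_down),
            "conserved_up": sorted(result.conserved_up)}

        communication, networks, centrality = {}, {}, {}
        if config.run_communication:
            stage = "communication"
            for offset, cond in enumerate(("control", "treated"), start=1):
                sub = norm[norm.obs["condition"] == cond].copy()
                params = dataclasses.replace(
                    config.comm, seed=(config.seed * 7919 + offset) % (2 ** 31))
                tensor = permutation_significance(sub, "cell_type",
                                                  cohort.lr_table, params)
                communication[cond] = tensor
                networks[cond] = aggregate_network(tensor)
                centrality[cond] = network_centrality(networks[cond][1])
            provenance["stages"][stage] = {
                c: {"clusters": len(t.clusters),
                    "interactions": len(t.interactions)}
                for c, t in communication.items()}

        stage = "enrichment"
        tested = sn_table.loc[sn_table["p_raw"].notna(), "gene"].tolist()
        query = sn_table.loc[sn_table["call"] != "ns", "gene"].tolist()
        collection = config.gene_sets or _default_gene_sets(cohort, tested)
        enrichment = None
        if collection is not None and query:
            enrichment = ora_hypergeometric(query, tested, collection)
        provenance["stages"][stage] = {
            "query": len(query), "universe": len(tested)}

        stage = "composition"
        per_sample, pooled = composition(
            filtered.obs[["sample", "condition", "cell_type"]])
    except Exception as exc:
        manifest = {"failed_stage": stage,
                    "completed": list(provenance["stages"])}
        if outdir is not None:
            Path(outdir).mkdir(parents=True, exist_ok=True)
            (Path(outdir) / "partial_manifest.json").write_text(
                json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    result_bundle = PipelineResult(
        qc_report=qc_report,
        de_tables={"snrna": sn_table, "pseudobulk": pb_table, "human": hs_table},
        directions=directions, rescue_mouse=rescue_mouse,
        rescue_human=rescue_human, integration=result, upset=upset,
        communication=communication, networks=networks, centrality=centrality,
        enrichment=enrichment, composition_per_sample=per_sample,
        composition_pooled=pooled, provenance=provenance)
    if outdir is not None:
        _write_results(result_bundle, outdir)
    return result_bundle


def _write_results(res: PipelineResult, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "qc_report.json").write_text(json.dumps(res.qc_report.to_dict(),
                                                   indent=1, sort_keys=True))
    for name, table in res.de_tables.items():
        txio.write_table(table, out / f"de_{name}.tsv")
    for name, table in res.directions.items():
        txio.write_table(table, out / f"directions_{name}.tsv")
    txio.write_table(res.upset, out / "upset_counts.tsv")
    integration = {
        "universe_size": len(res.integration.shared_universe),
        "rescue_mouse": {"n_responsive": res.rescue_mouse[0],
                         "n_reversed": res.rescue_mouse[1],
                         "fraction": res.rescue_mouse[2]},
        "rescue_human": {"n_responsive": res.rescue_human[0],
                         "n_reversed": res.rescue_human[1],
                         "fraction": res.rescue_human[2]},
        "conserved_down": sorted(res.integration.conserved_down),
        "conserved_up": sorted(res.integration.conserved_up),
    }
    (out / "integration_result.json").write_text(
        json.dumps(integration, indent=1, sort_keys=True))
    for cond, tensor in res.communication.items():
        txio.write_table(tensor.to_long(), out / f"communication_{cond}.tsv")
        count, strength, pathway = res.networks[cond]
        txio.write_table(count, out / f"network_count_{cond}.tsv", index=True)
        txio.write_table(strength, out / f"network_strength_{cond}.tsv", index=True)
        txio.write_table(pathway.to_frame(), out / f"pathway_strength_{cond}.tsv",
                         index=True)
        txio.write_table(res.centrality[cond], out / f"centrality_{cond}.tsv",
                         index=True)
    if res.enrichment is not None:
        txio.write_table(res.enrichment, out / "enrichment.tsv")
    txio.write_table(res.composition_per_sample, out / "composition_per_sample.tsv")
    txio.write_table(res.composition_pooled, out / "composition_pooled.tsv")
    (out / "provenance.json").write_text(json.dumps(res.provenance, indent=1,
                                                    sort_keys=True))
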