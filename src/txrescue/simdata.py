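"""Seed-reproducible synthetic cross-species cohort generator.

Emulates the statistical structure of a two-species glioma treatment study:
a single-nucleus RNA-seq arm (3 untreated + 2 treated mouse samples, negative
binomial counts, cell-type marker programs, a "damaged" high-mitochondrial
subpopulation) and a bulk RNA-seq arm (3 patients, paired treated/untreated
samples with shared patient intercepts), tied together by a one-to-one
ortholog map and a population-level cancer signature.  Treatment effects are
planted as multiplicative fold changes; a configurable subset of planted
genes runs *opposite* to its cancer direction ("rescued" genes), and exactly
one planted gene is cancer-up and treatment-down in every analysis — the
conserved target the downstream integration is expected to isolate.

The generator returns a :class:`PlantedTruth` record of everything it
planted, which the recovery tests compare against.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse
from scipy.stats import norm


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LRPairSpec:
    """One planted ligand-receptor channel.

    ``ligand``/``receptors`` name extra mouse genes appended to the matrix;
    their expression is concentrated in ``sender``/``receiver`` cell types.
    Multi-subunit receptors are allowed (all subunits boosted in the
    receiver).
    """

    interaction_id: str
    ligand: str
    receptors: tuple[str, ...]
    sender: str
    receiver: str
    pathway: str = "PLANTED"


def _default_lr_pairs() -> tuple[LRPairSpec, ...]:
    return (
        LRPairSpec("Lig0-Rec0", "Lig0", ("Rec0",), sender="type0",
                   receiver="type1", pathway="CHECKPOINT"),
    )


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the emulated study design: 3 control + 2 treated
    single-nucleus samples, 3 patients with paired bulk samples, a planted
    treatment effect of |log2FC| = 2 and one conserved cancer-up /
    treatment-down gene.
    """

    n_genes: int = 2000
    n_celltypes: int = 5
    cells_per_sample: int = 1500
    n_control_samples: int = 3
    n_treated_samples: int = 2
    n_patients: int = 3

    # abundance / noise model
    baseline_logmean: float = 0.0
    baseline_logsd: float = 1.2
    dispersion: float = 0.3            # NB dispersion scale; size = 1/dispersion
    dispersion_logsd: float = 0.3      # log-normal spread of per-gene dispersions
    libsize_logmean: float = 8.5       # per-cell library size ~ exp(N(8.5, .35)) ≈ 5k
    libsize_logsd: float = 0.35
    bulk_libsize_logmean: float = 14.5  # per-bulk-sample depth ≈ 2e6
    bulk_libsize_logsd: float = 0.1
    bulk_dispersion: float = 0.05
    patient_logsd: float = 0.3         # per-patient, per-gene intercept spread

    # mitochondrial / damaged-cell structure
    mito_gene_fraction: float = 0.01
    mito_baseline_share: float = 0.015  # fraction of a healthy cell's library
    mito_damaged_share: float = 0.15    # fraction of a damaged cell's library
    damaged_cell_fraction: float = 0.04

    # planted biology
    marker_multiplier: float = 8.0
    markers_per_type: int = 20
    treatment_lfc: float = 2.0
    n_cancer_up: int = 150
    n_cancer_down: int = 150
    n_rescued_planted: int = 40
    n_treatment_only: int = 60
    conserved_gene_id: str = "HGENE0001"
    treated_celltypes: tuple[str, ...] | None = None   # None = all cell types
    lr_pairs: tuple[LRPairSpec, ...] = field(default_factory=_default_lr_pairs)
    lr_baseline_rel: float = 1e-3      # off-target L/R abundance vs median gene

    ortholog_one2one_fraction: float = 0.8
    noncoding_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first offending field."""
        positive = ["n_genes", "n_celltypes", "cells_per_sample",
                    "n_control_samples", "n_treated_samples", "n_patients",
                    "dispersion", "bulk_dispersion", "markers_per_type"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        fractions = ["mito_gene_fraction", "damaged_cell_fraction",
                     "mito_baseline_share", "mito_damaged_share",
                     "noncoding_fraction"]
        for name in fractions:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if not 0.0 < self.ortholog_one2one_fraction <= 1.0:
            raise ValueError(
                f"ortholog_one2one_fraction must lie in (0, 1], got "
                f"{self.ortholog_one2one_fraction!r}")
        if self.marker_multiplier <= 1.0:
            raise ValueError(
                f"marker_multiplier must exceed 1, got {self.marker_multiplier!r}")
        for name in ["n_cancer_up", "n_cancer_down", "n_rescued_planted",
                     "n_treatment_only"]:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)!r}")
        if self.n_rescued_planted > 0 and self.n_cancer_up < 1:
            raise ValueError("n_cancer_up must be >= 1 to plant the conserved gene")
        n_mapped_needed = (self.n_cancer_up + self.n_cancer_down
                           + 2 * self.n_treatment_only)
        n_mappable = min(self.n_genes - math.ceil(self.mito_gene_fraction * self.n_genes),
                         self.n_genes)
        if math.floor(self.ortholog_one2one_fraction * n_mappable) < n_mapped_needed:
            raise ValueError(
                "n_genes: too few one-to-one orthologs to host the planted sets "
                f"(need {n_mapped_needed}, have "
                f"{math.floor(self.ortholog_one2one_fraction * n_mappable)})")


# ---------------------------------------------------------------------------
# planted truth
# ---------------------------------------------------------------------------

@dataclass
class PlantedTruth:
    """Record of everything the generator planted (canonical = human IDs)."""

    cancer_up_genes: frozenset[str]
    cancer_down_genes: frozenset[str]
    reversed_genes_mouse: frozenset[str]
    reversed_genes_human: frozenset[str]
    conserved_down_gene: str | None
    conserved_up_genes: frozenset[str]
    treatment_direction_mouse: dict[str, str]   # human ID -> up/down (treated vs control)
    treatment_direction_human: dict[str, str]
    celltype_markers: dict[str, frozenset[str]]  # cell type -> mouse gene IDs
    lr_assignments: tuple[LRPairSpec, ...]
    ortholog_map: pd.DataFrame                   # gene_human, gene_mouse, protein_coding
    mito_genes: frozenset[str]
    damaged_cells: frozenset[str]

    def __post_init__(self) -> None:
        if self.conserved_down_gene is not None:
            if self.conserved_down_gene not in self.cancer_up_genes:
                raise ValueError("conserved_down_gene must be cancer-up")
            if (self.conserved_down_gene not in self.reversed_genes_mouse
                    or self.conserved_down_gene not in self.reversed_genes_human):
                raise ValueError("conserved_down_gene must be reversed in both species")
        for col in ("gene_human", "gene_mouse"):
            if self.ortholog_map[col].duplicated().any():
                raise ValueError(f"ortholog map is not one-to-one in column {col}")

    def to_json(self) -> str:
        def _s(x):
            return sorted(x)
        payload = {
            "cancer_up_genes": _s(self.cancer_up_genes),
            "cancer_down_genes": _s(self.cancer_down_genes),
            "reversed_genes_mouse": _s(self.reversed_genes_mouse),
            "reversed_genes_human": _s(self.reversed_genes_human),
            "conserved_down_gene": self.conserved_down_gene,
            "conserved_up_genes": _s(self.conserved_up_genes),
            "treatment_direction_mouse": dict(sorted(self.treatment_direction_mouse.items())),
            "treatment_direction_human": dict(sorted(self.treatment_direction_human.items())),
            "celltype_markers": {k: _s(v) for k, v in sorted(self.celltype_markers.items())},
            "lr_assignments": [dataclasses.asdict(p) for p in self.lr_assignments],
            "ortholog_map": self.ortholog_map.to_dict(orient="list"),
            "mito_genes": _s(self.mito_genes),
            "damaged_cells": _s(self.damaged_cells),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def truth_summary(truth: PlantedTruth) -> pd.DataFrame:
    """Tabulate planted set sizes and memberships, one row per category."""
    rows = []

    def add(category: str, members) -> None:
        members = sorted(members)
        rows.append({"category": category, "n": len(members),
                     "members": ";".join(members)})

    add("cancer_up", truth.cancer_up_genes)
    add("cancer_down", truth.cancer_down_genes)
    add("reversed_mouse", truth.reversed_genes_mouse)
    add("reversed_human", truth.reversed_genes_human)
    add("conserved_down", [] if truth.conserved_down_gene is None
        else [truth.conserved_down_gene])
    add("conserved_up", truth.conserved_up_genes)
    for ct in sorted(truth.celltype_markers):
        add(f"markers:{ct}", truth.celltype_markers[ct])
    add("lr_ligands", {p.ligand for p in truth.lr_assignments})
    add("lr_receptors", {g for p in truth.lr_assignments for g in p.receptors})
    add("mito_genes", truth.mito_genes)
    return pd.DataFrame(rows, columns=["category", "n", "members"])


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Bundle returned by :func:`generate_cohort`."""

    snrna: ad.AnnData                 # cells x genes counts; obs: sample/condition/cell_type
    bulk_counts: pd.DataFrame         # genes x samples
    bulk_meta: pd.DataFrame           # sample, patient, treatment
    cancer_signature: pd.DataFrame    # gene, direction, log2fc, p_adj
    ortholog_map: pd.DataFrame        # gene_human, gene_mouse, protein_coding
    lr_table: pd.DataFrame            # interaction_id, ligand, receptor, pathway
    truth: PlantedTruth


# ---------------------------------------------------------------------------
# generation internals
# ---------------------------------------------------------------------------

def _elevated_weights(rng: np.random.Generator, cfg: CohortConfig, n: int) -> np.ndarray:
    # planted genes sit in the moderately-to-highly expressed range so that
    # recovery is limited by the measurement model, not by dropout
    q = rng.uniform(0.55, 0.9, size=n)
    return np.exp(cfg.baseline_logmean + cfg.baseline_logsd * norm.ppf(q))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size: np.ndarray) -> np.ndarray:
    p = size / (size + mean)
    return rng.negative_binomial(np.broadcast_to(size, mean.shape), p)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort plus its planted-truth record.

    Identical configs (including ``seed``) produce identical outputs.
    """
    config.validate()
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_genes, rng_cells, rng_sn, rng_bulk, rng_sig = (
        np.random.default_rng(s) for s in ss.spawn(5))

    # ---- gene universes --------------------------------------------------
    n_mito = math.ceil(cfg.mito_gene_fraction * cfg.n_genes)
    mouse_core = ([f"mt-Mgene{i:04d}" for i in range(n_mito)]
                  + [f"Mgene{i:04d}" for i in range(n_mito, cfg.n_genes)])
    lr_genes: list[str] = []
    for p in cfg.lr_pairs:
        for g in (p.ligand, *p.receptors):
            if g not in lr_genes:
                lr_genes.append(g)
    if set(lr_genes) & set(mouse_core):
        raise ValueError("lr_pairs: ligand/receptor names collide with core gene IDs")
    mouse_genes = mouse_core + lr_genes
    human_genes = [f"HGENE{i:04d}" for i in range(cfg.n_genes)]
    celltypes = [f"type{i}" for i in range(cfg.n_celltypes)]
    for p in cfg.lr_pairs:
        for ct in (p.sender, p.receiver):
            if ct not in celltypes:
                raise ValueError(f"lr_pairs: unknown cell type {ct!r}")
    if cfg.conserved_gene_id not in set(human_genes):
        raise ValueError(
            f"conserved_gene_id {cfg.conserved_gene_id!r} is not a human gene ID "
            f"(expected HGENE0000..HGENE{cfg.n_genes - 1:04d})")

    # ---- one-to-one ortholog map ----------------------------------------
    mappable_mouse = np.array(mouse_core[n_mito:])
    n_pairs = math.floor(cfg.ortholog_one2one_fraction
                         * min(len(mappable_mouse), cfg.n_genes))
    hm = rng_genes.choice(human_genes, size=n_pairs, replace=False)
    if cfg.conserved_gene_id not in hm:
        hm[rng_genes.integers(n_pairs)] = cfg.conserved_gene_id
    mm = rng_genes.choice(mappable_mouse, size=n_pairs, replace=False)
    human_to_mouse = dict(zip(hm.tolist(), mm.tolist()))

    # ---- planted gene sets (human / canonical IDs) -----------------------
    mapped_humans = list(hm)
    order = rng_genes.permutation(len(mapped_humans))
    shuffled = [mapped_humans[i] for i in order]
    shuffled.remove(cfg.conserved_gene_id)
    shuffled.insert(0, cfg.conserved_gene_id)   # conserved gene goes to cancer_up

    cancer_up = shuffled[:cfg.n_cancer_up]
    cancer_down = shuffled[cfg.n_cancer_up:cfg.n_cancer_up + cfg.n_cancer_down]
    rest = shuffled[cfg.n_cancer_up + cfg.n_cancer_down:]
    cancer_dir = {g: "up" for g in cancer_up}
    cancer_dir.update({g: "down" for g in cancer_down})

    conserved: str | None = None
    reversed_mouse: list[str] = []
    reversed_human: list[str] = []
    if cfg.n_rescued_planted > 0:
        conserved = cfg.conserved_gene_id
        pool = [g for g in cancer_up + cancer_down if g != conserved]
        k = min(cfg.n_rescued_planted - 1, len(pool) // 2)
        reversed_mouse = [conserved] + pool[:k]
        reversed_human = [conserved] + pool[k:2 * k]

    to_pool = rest[:2 * cfg.n_treatment_only]
    to_dir = {g: ("up" if rng_genes.random() < 0.5 else "down") for g in to_pool}
    treatment_only_mouse = list(rng_genes.choice(to_pool, size=min(cfg.n_treatment_only, len(to_pool)),
                                                 replace=False)) if to_pool else []
    treatment_only_human = list(rng_genes.choice(to_pool, size=min(cfg.n_treatment_only, len(to_pool)),
                                                 replace=False)) if to_pool else []

    def _treat_dirs(reversed_set: list[str], only_set: list[str]) -> dict[str, str]:
        d = {g: ("down" if cancer_dir[g] == "up" else "up") for g in reversed_set}
        d.update({g: to_dir[g] for g in only_set})
        return d

    tdir_mouse = _treat_dirs(reversed_mouse, treatment_only_mouse)
    tdir_human = _treat_dirs(reversed_human, treatment_only_human)

    # ---- cell-type markers (mouse IDs) -----------------------------------
    planted_mouse = {human_to_mouse[g] for g in tdir_mouse}
    marker_pool = [g for g in mouse_core[n_mito:] if g not in planted_mouse]
    marker_pick = rng_genes.choice(marker_pool,
                                   size=cfg.markers_per_type * cfg.n_celltypes,
                                   replace=False)
    markers = {ct: frozenset(marker_pick[i * cfg.markers_per_type:(i + 1) * cfg.markers_per_type])
               for i, ct in enumerate(celltypes)}

    # ---- mouse gene weights ----------------------------------------------
    n_mouse = len(mouse_genes)
    w = rng_genes.lognormal(cfg.baseline_logmean, cfg.baseline_logsd, size=n_mouse)
    gene_index = {g: i for i, g in enumerate(mouse_genes)}
    planted_idx = np.array([gene_index[g] for g in sorted(planted_mouse)], dtype=int)
    if planted_idx.size:
        w[planted_idx] = _elevated_weights(rng_genes, cfg, planted_idx.size)
    med_w = float(np.median(w[:cfg.n_genes]))
    for g in lr_genes:
        w[gene_index[g]] = cfg.lr_baseline_rel * med_w
    lr_boost = np.exp(cfg.baseline_logmean + cfg.baseline_logsd * norm.ppf(0.85)) \
        * cfg.marker_multiplier

    size_sn = 1.0 / (cfg.dispersion
                     * rng_genes.lognormal(0.0, cfg.dispersion_logsd, size=n_mouse))

    # ---- snRNA samples ----------------------------------------------------
    samples = ([f"CN{i + 1}" for i in range(cfg.n_control_samples)]
               + [f"TN{i + 1}" for i in range(cfg.n_treated_samples)])
    conditions = (["control"] * cfg.n_control_samples
                  + ["treated"] * cfg.n_treated_samples)
    treated_cts = set(celltypes if cfg.treated_celltypes is None
                      else cfg.treated_celltypes)
    type_probs = np.linspace(0.8, 1.2, cfg.n_celltypes)
    type_probs = type_probs / type_probs.sum()

    lfc_mult_mouse = np.ones(n_mouse)
    for g, d in tdir_mouse.items():
        lfc_mult_mouse[gene_index[human_to_mouse[g]]] = \
            2.0 ** (cfg.treatment_lfc if d == "up" else -cfg.treatment_lfc)

    mito_mask = np.zeros(n_mouse, dtype=bool)
    mito_mask[:n_mito] = True

    def _group_props(celltype: str, treated: bool, damaged: bool) -> np.ndarray:
        p = w.copy()
        for g in markers[celltype]:
            p[gene_index[g]] *= cfg.marker_multiplier
        for pair in cfg.lr_pairs:
            if pair.sender == celltype:
                p[gene_index[pair.ligand]] = lr_boost
            if pair.receiver == celltype:
                for g in pair.receptors:
                    p[gene_index[g]] = lr_boost
        if treated and celltype in treated_cts:
            p = p * lfc_mult_mouse
        share = cfg.mito_damaged_share if damaged else cfg.mito_baseline_share
        if n_mito:
            p_m, p_r = p[mito_mask], p[~mito_mask]
            p[mito_mask] = share * p_m / p_m.sum()
            p[~mito_mask] = (1.0 - share) * p_r / p_r.sum()
            return p
        return p / p.sum()

    blocks, obs_rows = [], []
    for sample, condition in zip(samples, conditions):
        n_cells = cfg.cells_per_sample
        cts = rng_cells.choice(cfg.n_celltypes, size=n_cells, p=type_probs)
        damaged = rng_cells.random(n_cells) < cfg.damaged_cell_fraction
        libs = rng_cells.lognormal(cfg.libsize_logmean, cfg.libsize_logsd, size=n_cells)
        counts = np.zeros((n_cells, n_mouse), dtype=np.int64)
        for ct_i in range(cfg.n_celltypes):
            for dmg in (False, True):
                mask = (cts == ct_i) & (damaged == dmg)
                if not mask.any():
                    continue
                props = _group_props(celltypes[ct_i], condition == "treated", dmg)
                mu = libs[mask, None] * props[None, :]
                counts[mask] = _nb_draw(rng_sn, mu, size_sn[None, :])
        blocks.append(sparse.csr_matrix(counts))
        for i in range(n_cells):
            obs_rows.append((f"{sample}_cell{i:05d}", sample, condition,
                             celltypes[cts[i]], bool(damaged[i])))

    obs = pd.DataFrame(obs_rows, columns=["barcode", "sample", "condition",
                                          "cell_type", "damaged"]).set_index("barcode")
    var = pd.DataFrame(index=pd.Index(mouse_genes, name="gene"))
    var["mito"] = mito_mask
    snrna = ad.AnnData(X=sparse.vstack(blocks).tocsr(), obs=obs, var=var)

    # ---- bulk human samples ----------------------------------------------
    hw = rng_genes.lognormal(cfg.baseline_logmean, cfg.baseline_logsd, size=cfg.n_genes)
    h_index = {g: i for i, g in enumerate(human_genes)}
    planted_h = sorted(set(tdir_human) | set(cancer_dir))
    idx_h = np.array([h_index[g] for g in planted_h], dtype=int)
    if idx_h.size:
        hw[idx_h] = _elevated_weights(rng_genes, cfg, idx_h.size)
    size_bulk = 1.0 / (cfg.bulk_dispersion
                       * rng_genes.lognormal(0.0, cfg.dispersion_logsd, size=cfg.n_genes))

    lfc_mult_h = np.ones(cfg.n_genes)
    for g, d in tdir_human.items():
        lfc_mult_h[h_index[g]] = 2.0 ** (cfg.treatment_lfc if d == "up"
                                         else -cfg.treatment_lfc)

    bulk_cols, meta_rows = {}, []
    for p_i in range(cfg.n_patients):
        patient = f"P{p_i + 1}"
        intercept = rng_bulk.lognormal(0.0, cfg.patient_logsd, size=cfg.n_genes)
        for treated in (False, True):
            name = f"{patient}_{'trt' if treated else 'ctrl'}"
            props = hw * intercept * (lfc_mult_h if treated else 1.0)
            props = props / props.sum()
            depth = rng_bulk.lognormal(cfg.bulk_libsize_logmean, cfg.bulk_libsize_logsd)
            mu = depth * props
            bulk_cols[name] = _nb_draw(rng_bulk, mu, size_bulk)
            meta_rows.append((name, patient, "treated" if treated else "control"))
    bulk_counts = pd.DataFrame(bulk_cols, index=pd.Index(human_genes, name="gene"))
    bulk_meta = pd.DataFrame(meta_rows, columns=["sample", "patient", "treatment"]
                             ).set_index("sample")

    # ---- population cancer signature --------------------------------------
    sig_dir = np.array(["ns"] * cfg.n_genes, dtype=object)
    sig_lfc = rng_sig.normal(0.0, 0.3, size=cfg.n_genes)
    sig_p = rng_sig.uniform(0.2, 1.0, size=cfg.n_genes)
    for g, d in cancer_dir.items():
        i = h_index[g]
        sig_dir[i] = d
        mag = 1.5 + abs(rng_sig.normal(0.0, 0.75))
        sig_lfc[i] = mag if d == "up" else -mag
        sig_p[i] = 10.0 ** rng_sig.uniform(-12.0, -3.0)
    cancer_signature = pd.DataFrame({
        "gene": human_genes, "direction": sig_dir,
        "log2fc": sig_lfc, "p_adj": sig_p})

    # ---- ortholog map / LR table / truth ----------------------------------
    coding = np.ones(n_pairs, dtype=bool)
    planted_set = set(planted_h)
    unplanted_rows = [i for i, g in enumerate(hm) if g not in planted_set]
    n_nc = math.floor(cfg.noncoding_fraction * len(unplanted_rows))
    if n_nc:
        nc_rows = rng_genes.choice(unplanted_rows, size=n_nc, replace=False)
        coding[nc_rows] = False
    ortholog_map = pd.DataFrame({"gene_human": hm, "gene_mouse": mm,
                                 "protein_coding": coding})
    ortholog_map = ortholog_map.sort_values("gene_human", ignore_index=True)

    lr_table = pd.DataFrame(
        [(p.interaction_id, p.ligand, "+".join(p.receptors), p.pathway)
         for p in cfg.lr_pairs],
        columns=["interaction_id", "ligand", "receptor", "pathway"])

    conserved_up = frozenset(reversed_mouse) & frozenset(reversed_human) \
        & frozenset(cancer_down)
    truth = PlantedTruth(
        cancer_up_genes=frozenset(cancer_up),
        cancer_down_genes=frozenset(cancer_down),
        reversed_genes_mouse=frozenset(reversed_mouse),
        reversed_genes_human=frozenset(reversed_human),
        conserved_down_gene=conserved,
        conserved_up_genes=conserved_up,
        treatment_direction_mouse=tdir_mouse,
        treatment_direction_human=tdir_human,
        celltype_markers=markers,
        lr_assignments=tuple(cfg.lr_pairs),
        ortholog_map=ortholog_map,
        mito_genes=frozenset(mouse_core[:n_mito]),
        damaged_cells=frozenset(obs.index[obs["damaged"]]),
    )
    return SyntheticCohort(snrna=snrna, bulk_counts=bulk_counts,
                           bulk_meta=bulk_meta,
                           cancer_signature=cancer_signature,
                           ortholog_map=ortholog_map, lr_table=lr_table,
                           truth=truth)
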