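"""Ligand-receptor cell-cell communication inference.

Cluster-level signaling is scored with a saturating mass-action form: for
sender i and receiver j, the raw probability of an interaction is
(L_i * R_j) / (K + L_i * R_j), where L is the truncated-mean ligand
expression in the sender, R the geometric mean of truncated-mean receptor
subunit expression in the receiver, and K a half-saturation constant.  With
population-size scaling the score is further multiplied by the product of
the clusters' cell-count fractions, favoring abundant populations.
Significance comes from a label-permutation null; aggregated count/strength
networks and sender/receiver/influence centralities summarize the result.

Clusters below ``min_cells`` are removed before scoring.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CommParams:
    trim: float = 0.13
    min_cells: int = 20
    half_saturation: float = 0.5
    population_size_scaling: bool = True
    n_permutations: int = 100
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.trim <= 0.25:
            raise ValueError("trim must lie in [0, 0.25]")
        if self.min_cells < 1:
            raise ValueError("min_cells must be positive")
        if self.half_saturation <= 0:
            raise ValueError("half_saturation must be positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")


@dataclass
class CommunicationTensor:
    """sender x receiver x interaction probabilities (+ permutation p-values)."""

    clusters: list[str]
    interactions: list[str]
    pathways: dict[str, str]
    prob: np.ndarray                      # (n_clusters, n_clusters, n_interactions)
    pval: np.ndarray | None = None
    cluster_sizes: pd.Series | None = None

    def to_long(self) -> pd.DataFrame:
        rows = []
        for si, s in enumerate(self.clusters):
            for ri, r in enumerate(self.clusters):
                for ii, inter in enumerate(self.interactions):
                    rows.append((s, r, inter, self.prob[si, ri, ii],
                                 np.nan if self.pval is None
                                 else self.pval[si, ri, ii]))
        return pd.DataFrame(rows, columns=["sender", "receiver", "interaction",
                                           "prob", "pval"])

    def pathway_strength(self) -> pd.Series:
        strength: dict[str, float] = {}
        for ii, inter in enumerate(self.interactions):
            pw = self.pathways.get(inter, "unassigned")
            strength[pw] = strength.get(pw, 0.0) + float(self.prob[:, :, ii].sum())
        return pd.Series(strength, name="strength").sort_index()


def truncated_mean(values, trim: float) -> float:
    """Mean after dropping floor(n*trim) values from each tail; trim 0 is the
    plain mean."""
    v = np.sort(np.asarray(values, dtype=np.float64))
    n = v.size
    if n == 0:
        raise ValueError("truncated_mean requires at least one value")
    k = math.floor(n * trim)
    if 2 * k >= n:
        k = (n - 1) // 2
    return float(v[k:n - k].mean())


def _truncated_means_matrix(X: np.ndarray, trim: float) -> np.ndarray:
    """Column-wise truncated mean of a dense cells x genes block."""
    n = X.shape[0]
    k = math.floor(n * trim)
    if 2 * k >= n:
        k = (n - 1) // 2
    if k == 0:
        return X.mean(axis=0)
    Xs = np.sort(X, axis=0)
    return Xs[k:n - k].mean(axis=0)


def cluster_expression(adata: ad.AnnData, cluster_key: str, genes,
                       params: CommParams = CommParams()) -> pd.DataFrame:
    """Truncated-mean expression per retained cluster (rows) and gene (cols).

    Clusters with fewer than ``params.min_cells`` cells are dropped (logged).
    """
    genes = [g for g in genes]
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        raise KeyError(f"genes absent from the assay: {missing}")
    labels = adata.obs[cluster_key].astype(str)
    sizes = labels.value_counts()
    kept = sorted(sizes.index[sizes >= params.min_cells])
    dropped = sorted(set(sizes.index) - set(kept))
    if dropped:
        log.info("cluster_expression: dropping clusters below min_cells=%d: %s",
                 params.min_cells, dropped)
    if not kept:
        raise ValueError("no cluster reaches min_cells; nothing to score")

    sub = adata[:, genes]
    X = sub.X
    X = np.asarray(X.todense() if sparse.issparse(X) else X, dtype=np.float64)
    rows = {}
    lab_arr = labels.to_numpy()
    for cl in kept:
        rows[cl] = _truncated_means_matrix(X[lab_arr == cl], params.trim)
    return pd.DataFrame.from_dict(rows, orient="index", columns=genes)


def _lr_levels(expr: pd.DataFrame, lr_table: pd.DataFrame):
    """Per-interaction ligand vector and receptor (geometric-mean) vector."""
    usable = []
    for _, row in lr_table.iterrows():
        subunits = str(row["receptor"]).split("+")
        needed = [row["ligand"], *subunits]
        if all(g in expr.columns for g in needed):
            usable.append((row["interaction_id"], row["ligand"], subunits,
                           row.get("pathway", "unassigned")))
        else:
            log.info("skipping interaction %r: gene(s) missing from matrix",
                     row["interaction_id"])
    return usable


def communication_probability(expr: pd.DataFrame, cluster_sizes: pd.Series,
                              lr_table: pd.DataFrame,
                              params: CommParams = CommParams()
                              ) -> CommunicationTensor:
    """Saturating interaction probabilities for every sender/receiver pair.

    raw = L*R / (K + L*R); with population-size scaling the value is
    multiplied by (n_sender/N)(n_receiver/N) over retained cells N.
    """
    clusters = list(expr.index)
    usable = _lr_levels(expr, lr_table)
    n_c, n_i = len(clusters), len(usable)
    prob = np.zeros((n_c, n_c, n_i))
    sizes = cluster_sizes.loc[clusters].to_numpy(dtype=np.float64)
    N = sizes.sum()
    pathways = {}
    for ii, (inter, ligand, subunits, pathway) in enumerate(usable):
        pathways[inter] = pathway
        L = expr[ligand].to_numpy()
        R = np.exp(np.mean(np.log(np.maximum(
            expr[subunits].to_numpy(), 0.0) + 1e-300), axis=1))
        R[np.min(expr[subunits].to_numpy(), axis=1) <= 0] = 0.0
        LR = np.outer(L, R)
        raw = LR / (params.half_saturation + LR)
        if params.population_size_scaling:
            raw = raw * np.outer(sizes / N, sizes / N)
        prob[:, :, ii] = raw
    return CommunicationTensor(clusters=clusters,
                               interactions=[u[0] for u in usable],
                               pathways=pathways, prob=prob,
                               cluster_sizes=pd.Series(sizes, index=clusters))


def permutation_significance(adata: ad.AnnData, cluster_key: str,
                             lr_table: pd.DataFrame,
                             params: CommParams = CommParams()
                             ) -> CommunicationTensor:
    """Observed probabilities with label-permutation p-values.

    pval = (1 + #{permuted >= observed}) / (n_permutations + 1); entries with
    pval > alpha have their probability zeroed.  Deterministic given
    ``params.seed``.
    """
    genes = sorted({g for _, row in lr_table.iterrows()
                    for g in [row["ligand"], *str(row["receptor"]).split("+")]
                    if g in adata.var_names})
    labels = adata.obs[cluster_key].astype(str)
    sizes = labels.value_counts()
    kept = sorted(sizes.index[sizes >= params.min_cells])
    if not kept:
        raise ValueError("no cluster reaches min_cells; nothing to score")
    keep_mask = labels.isin(kept).to_numpy()
    sub = adata[keep_mask, genes]
    X = sub.X
    X = np.asarray(X.todense() if sparse.issparse(X) else X, dtype=np.float64)
    lab = labels.to_numpy()[keep_mask]
    cluster_sizes = pd.Series({cl: int((lab == cl).sum()) for cl in kept})

    def _tensor_for(lab_vec: np.ndarray) -> CommunicationTensor:
        expr = pd.DataFrame.from_dict(
            {cl: _truncated_means_matrix(X[lab_vec == cl], params.trim)
             for cl in kept}, orient="index", columns=genes)
        return communication_probability(expr, cluster_sizes, lr_table, params)

    observed = _tensor_for(lab)
    rng = np.random.default_rng(params.seed)
    exceed = np.zeros_like(observed.prob)
    for _ in range(params.n_permutations):
        perm = rng.permutation(lab)
        exceed += _tensor_for(perm).prob >= observed.prob - 1e-15
    pval = (1.0 + exceed) / (params.n_permutations + 1.0)
    pval[observed.prob <= 0] = 1.0
    filtered = np.where(pval <= params.alpha, observed.prob, 0.0)
    return CommunicationTensor(clusters=observed.clusters,
                               interactions=observed.interactions,
                               pathways=observed.pathways,
                               prob=filtered, pval=pval,
                               cluster_sizes=observed.cluster_sizes)


def aggregate_network(tensor: CommunicationTensor
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Count and strength matrices plus per-pathway total strength."""
    count = (tensor.prob > 0).sum(axis=2)
    strength = tensor.prob.sum(axis=2)
    idx = pd.Index(tensor.clusters, name="sender")
    cols = pd.Index(tensor.clusters, name="receiver")
    return (pd.DataFrame(count, index=idx, columns=cols),
            pd.DataFrame(strength, index=idx, columns=cols),
            tensor.pathway_strength())


def network_centrality(strength: pd.DataFrame) -> pd.DataFrame:
    """Sender, receiver and influence scores per cluster, each scaled to [0, 1].

    Sender = outgoing strength (row sums), receiver = incoming (column sums),
    influence = their sum; all-zero score vectors stay at zero.
    """
    out = strength.sum(axis=1).to_numpy(dtype=np.float64)
    incoming = strength.sum(axis=0).to_numpy(dtype=np.float64)
    influence = out + incoming

    def _scale(v: np.ndarray) -> np.ndarray:
        m = v.max()
        return v / m if m > 0 else v

    return pd.DataFrame({"sender": _scale(out), "receiver": _scale(incoming),
                         "influence": _scale(influence)},
                        index=strength.index)
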