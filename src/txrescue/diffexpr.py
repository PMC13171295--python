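"""Differential-expression engines.

Three engines share one significance vocabulary:

* single-cell rank-sum DE (two-sided Wilcoxon; exact enumeration for tiny
  groups, tie-corrected normal approximation otherwise);
* pseudo-bulk DE (per-sample count aggregation, low-expression filtering,
  TMM between-sample normalization, precision-weighted log-CPM transform and
  an empirical-Bayes moderated t-test);
* paired bulk DE (the same moderated linear model with a patient blocking
  factor absorbing between-patient baselines).

The moderated test shrinks gene-wise residual variances toward a pooled
prior estimated by moment-matching log s^2 to a scaled chi-square; with
prior df = 0 it reduces exactly to the ordinary per-gene weighted t-test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse, stats
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# significance profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignificanceProfile:
    """Effect-size / significance thresholds attached to a DE run.

    All comparisons are strict: a gene is called when |log2FC| > ``lfc_min``
    and its (adjusted, if ``use_fdr``) p-value is < ``p_max``.
    """

    lfc_min: float
    p_max: float = 0.05
    use_fdr: bool = True
    min_pct: float | None = None

    def __post_init__(self) -> None:
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be nonnegative")
        if not 0.0 < self.p_max <= 1.0:
            raise ValueError("p_max must lie in (0, 1]")
        if self.min_pct is not None and not 0.0 <= self.min_pct <= 1.0:
            raise ValueError("min_pct must lie in [0, 1]")


#: The four threshold profiles used across the analyses.
PROFILES: dict[str, SignificanceProfile] = {
    # single-nucleus: |log2FC| > 0.58, FDR < 0.05, expressed in > 10% of cells
    "snrna": SignificanceProfile(lfc_min=0.58, p_max=0.05, use_fdr=True, min_pct=0.10),
    # pseudo-bulk: FDR < 0.05 and |log2FC| > 1
    "pseudobulk": SignificanceProfile(lfc_min=1.0, p_max=0.05, use_fdr=True),
    # human paired bulk: raw P < 0.05 and |log2FC| > 1
    "human": SignificanceProfile(lfc_min=1.0, p_max=0.05, use_fdr=False),
    # population-level cancer signature: FDR < 0.05 and |log2FC| > 1
    "population": SignificanceProfile(lfc_min=1.0, p_max=0.05, use_fdr=True),
}


@dataclass
class DesignSpec:
    """Two-condition design with an optional blocking factor."""

    condition: tuple[str, ...]
    blocking: tuple[str, ...] | None = None
    contrast: tuple[str, str] = ("treated", "control")

    def __post_init__(self) -> None:
        self.condition = tuple(self.condition)
        if self.blocking is not None:
            self.blocking = tuple(self.blocking)
            if len(self.blocking) != len(self.condition):
                raise ValueError("blocking labels must match condition labels in length")
        levels = set(self.condition)
        if not levels <= set(self.contrast):
            raise ValueError(f"condition labels {levels} outside contrast {self.contrast}")

    @property
    def group_sizes(self) -> dict[str, int]:
        return {lvl: self.condition.count(lvl) for lvl in set(self.condition)}

    def matrix(self) -> tuple[np.ndarray, int]:
        """Design matrix (intercept, blocking dummies, treatment) and the
        column index of the treatment coefficient."""
        n = len(self.condition)
        cols = [np.ones(n)]
        if self.blocking is not None:
            levels = list(dict.fromkeys(self.blocking))
            for lvl in levels[1:]:
                cols.append(np.array([1.0 if b == lvl else 0.0 for b in self.blocking]))
        cols.append(np.array([1.0 if c == self.contrast[0] else 0.0
                              for c in self.condition]))
        X = np.column_stack(cols)
        return X, X.shape[1] - 1


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def lognormalize(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Total-count normalize and log-transform: ln(1 + count/total x scale).

    All-zero cells map to zeros.  Raw counts are preserved in
    ``layers['counts']``.
    """
    out = adata.copy()
    X = out.X
    if sparse.issparse(X):
        X = X.tocsr().astype(np.float64)
        totals = np.asarray(X.sum(axis=1)).ravel()
        inv = np.where(totals > 0, scale / np.maximum(totals, 1.0), 0.0)
        norm = X.copy()
        norm.data = np.log1p(X.data * np.repeat(inv, np.diff(X.indptr)))
        out.layers["counts"] = adata.X.copy()
        out.X = norm
    else:
        X = np.asarray(X, dtype=np.float64)
        totals = X.sum(axis=1)
        inv = np.where(totals > 0, scale / np.maximum(totals, 1.0), 0.0)
        out.layers["counts"] = np.asarray(adata.X).copy()
        out.X = np.log1p(X * inv[:, None])
    return out


# ---------------------------------------------------------------------------
# single-cell rank-sum engine
# ---------------------------------------------------------------------------

def _exact_rank_p(xa: np.ndarray, xb: np.ndarray,
                  combos: np.ndarray | None = None) -> float:
    """Two-sided exact rank-sum p by enumeration of all group assignments.

    Uses mid-ranks, so full ties give p = 1.  ``combos`` may carry the cached
    ``C(n, n_a)`` index array for repeated calls at the same group sizes.
    """
    n_a, n_b = len(xa), len(xb)
    pooled = np.concatenate([xa, xb])
    ranks = stats.rankdata(pooled)
    obs = ranks[:n_a].sum()
    mu = n_a * (n_a + n_b + 1) / 2.0
    if combos is None:
        combos = np.array(list(itertools.combinations(range(n_a + n_b), n_a)))
    sums = ranks[combos].sum(axis=1)
    return float(np.mean(np.abs(sums - mu) >= np.abs(obs - mu) - 1e-9))


def _ranksum_normal_p(Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
    """Vectorized two-sided rank-sum p, tie-corrected normal approximation
    with continuity correction (columns = genes)."""
    n_a, n_b = Xa.shape[0], Xb.shape[0]
    n = n_a + n_b
    pooled = np.concatenate([Xa, Xb], axis=0)
    ranks = stats.rankdata(pooled, axis=0)
    R_a = ranks[:n_a].sum(axis=0)
    U = R_a - n_a * (n_a + 1) / 2.0
    mu = n_a * n_b / 2.0

    # per-gene tie term sum(t^3 - t) from sorted columns
    xs = np.sort(pooled, axis=0)
    tie = np.empty(pooled.shape[1])
    for j in range(pooled.shape[1]):
        bounds = np.flatnonzero(xs[1:, j] != xs[:-1, j])
        t = np.diff(np.concatenate([[-1], bounds, [n - 1]]))
        tie[j] = np.sum(t ** 3 - t)

    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie / (n * (n - 1.0)))
    dev = np.maximum(np.abs(U - mu) - 0.5, 0.0)       # continuity correction
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma2 > 0, dev / np.sqrt(np.maximum(sigma2, 1e-300)), 0.0)
    p = np.clip(2.0 * stats.norm.sf(z), 0.0, 1.0)
    p[sigma2 <= 0] = 1.0                              # fully tied genes
    return p


def de_wilcoxon(adata: ad.AnnData, group_a: str, group_b: str,
                profile: SignificanceProfile = PROFILES["snrna"],
                groupby: str = "condition",
                max_exact: int = 8) -> pd.DataFrame:
    """Per-gene two-sided rank-sum DE on a log-normalized assay.

    ``group_a`` vs ``group_b`` are levels of ``obs[groupby]``; log2FC is
    computed on the de-logged scale as log2((mean expm1 a + 1)/(mean expm1 b
    + 1)).  Genes expressed in at most ``min_pct`` of cells in *both* groups
    are not tested (call = ns, p = NaN); BH runs across tested genes.
    """
    labels = adata.obs[groupby].to_numpy()
    mask_a = labels == group_a
    mask_b = labels == group_b
    for name, mask in (("group_a", mask_a), ("group_b", mask_b)):
        if not mask.any():
            raise ValueError(f"{name} ({group_a if name == 'group_a' else group_b!r}) "
                             "selects no cells")

    X = adata.X
    Xa = np.asarray(X[mask_a].todense() if sparse.issparse(X) else X[mask_a],
                    dtype=np.float64)
    Xb = np.asarray(X[mask_b].todense() if sparse.issparse(X) else X[mask_b],
                    dtype=np.float64)
    n_a, n_b = Xa.shape[0], Xb.shape[0]

    pct_a = (Xa > 0).mean(axis=0)
    pct_b = (Xb > 0).mean(axis=0)
    mean_a = np.expm1(Xa).mean(axis=0)
    mean_b = np.expm1(Xb).mean(axis=0)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))

    if profile.min_pct is None:
        testable = np.ones(adata.n_vars, dtype=bool)
    else:
        testable = (pct_a > profile.min_pct) | (pct_b > profile.min_pct)

    p_raw = np.full(adata.n_vars, np.nan)
    idx = np.flatnonzero(testable)
    if idx.size:
        if n_a <= max_exact and n_b <= max_exact:
            combos = np.array(list(itertools.combinations(range(n_a + n_b), n_a)))
            for j in idx:
                p_raw[j] = _exact_rank_p(Xa[:, j], Xb[:, j], combos)
        else:
            p_raw[idx] = _ranksum_normal_p(Xa[:, idx], Xb[:, idx])

    p_adj = np.full(adata.n_vars, np.nan)
    if idx.size:
        p_adj[idx] = multipletests(p_raw[idx], method="fdr_bh")[1]

    table = pd.DataFrame({
        "gene": adata.var_names, "log2fc": log2fc,
        "p_raw": p_raw, "p_adj": p_adj,
        "pct_a": pct_a, "pct_b": pct_b,
        "mean_a": mean_a, "mean_b": mean_b,
    })
    table["call"] = _calls(table, profile)
    table.loc[~testable, "call"] = "ns"
    return table


# ---------------------------------------------------------------------------
# pseudo-bulk construction and filtering
# ---------------------------------------------------------------------------

def pseudobulk(adata: ad.AnnData, sample_key: str = "sample") -> pd.DataFrame:
    """Sum counts over cells sharing a sample label (genes x samples).

    Column order follows first appearance of each label.
    """
    labels = adata.obs[sample_key].astype(str).to_numpy()
    order = list(dict.fromkeys(labels))
    X = adata.layers["counts"] if "counts" in adata.layers else adata.X
    cols = {}
    for lab in order:
        sub = X[labels == lab]
        cols[lab] = np.asarray(sub.sum(axis=0)).ravel()
    return pd.DataFrame(cols, index=pd.Index(adata.var_names, name="gene"))


def filter_low_expression(pb: pd.DataFrame, design: DesignSpec,
                          min_count: int = 10, min_total: int = 15) -> pd.DataFrame:
    """Drop weakly expressed genes before normalization.

    A gene is kept when its CPM reaches the CPM equivalent of ``min_count``
    reads in the median library in at least k samples (k = smallest condition
    group), and its total count is at least ``min_total``.
    """
    if pb.shape[1] < 2:
        raise ValueError("filter_low_expression requires at least 2 samples")
    lib = pb.sum(axis=0).to_numpy(dtype=np.float64)
    cpm = pb.to_numpy(dtype=np.float64) / np.maximum(lib, 1.0) * 1e6
    cpm_cutoff = min_count / np.median(lib) * 1e6
    k = min(design.group_sizes.values())
    keep = ((cpm >= cpm_cutoff).sum(axis=1) >= k) & \
        (pb.sum(axis=1).to_numpy() >= min_total)
    return pb.loc[keep]


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def tmm_factors(pb: pd.DataFrame, trim_m: float = 0.3,
                trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors (geometric mean 1).

    The reference sample is the one whose 75th-percentile CPM is closest to
    the mean of those percentiles.  Per sample, log-ratios M vs the reference
    are trimmed two-sided (30% on M, 5% on mean abundance A) and averaged
    with inverse asymptotic-binomial-variance weights.
    """
    counts = pb.to_numpy(dtype=np.float64)
    if counts.shape[1] < 2:
        raise ValueError("tmm_factors requires at least 2 samples")
    lib = counts.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("tmm_factors requires nonzero library sizes")
    f75 = np.array([np.quantile(counts[:, j], 0.75) / lib[j]
                    for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    log_factors = np.zeros(counts.shape[1])
    obs_r = counts[:, ref] / lib[ref]
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        obs_j = counts[:, j] / lib[j]
        fin = (counts[:, j] > 0) & (counts[:, ref] > 0)
        if not fin.any():
            raise ValueError(
                f"sample {pb.columns[j]!r} shares no nonzero genes with the reference")
        M = np.log2(obs_j[fin] / obs_r[fin])
        A = 0.5 * np.log2(obs_j[fin] * obs_r[fin])
        w = ((lib[j] - counts[fin, j]) / (lib[j] * counts[fin, j])
             + (lib[ref] - counts[fin, ref]) / (lib[ref] * counts[fin, ref]))
        n = M.size
        lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
        rank_m = stats.rankdata(M)
        rank_a = stats.rankdata(A)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & \
            (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.any() and np.sum(1.0 / w[keep]) > 0:
            log_factors[j] = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
        # else: leave at 0 (factor 1) — degenerate trim
    log_factors -= log_factors.mean()   # geometric mean of factors = 1
    return pd.Series(2.0 ** log_factors, index=pb.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# precision-weighted transform
# ---------------------------------------------------------------------------

def precision_weighted_transform(
        pb: pd.DataFrame, factors: pd.Series, design: DesignSpec,
        span: float = 0.5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-CPM with observation-level precision weights.

    logCPM = log2((count + 0.5)/(libsize x factor + 1) x 1e6); a lowess trend
    (given span, flat extrapolation) of sqrt residual standard deviation
    against mean log-CPM supplies each observation's weight as trend^-4 at
    its fitted value.  Weights are strictly positive.
    """
    X, _ = design.matrix()
    n, p = X.shape
    if pb.shape[1] != n:
        raise ValueError("design length does not match the number of samples")
    if n < p:
        raise ValueError("fewer samples than design columns")

    counts = pb.to_numpy(dtype=np.float64)
    lib = counts.sum(axis=0) * factors.loc[pb.columns].to_numpy()
    logcpm = np.log2((counts + 0.5) / (lib + 1.0)[None, :] * 1e6)

    pinv = np.linalg.pinv(X)
    beta = logcpm @ pinv.T                       # genes x p
    fitted = beta @ X.T
    resid = logcpm - fitted
    d = n - np.linalg.matrix_rank(X)
    if d <= 0:
        raise ValueError("design leaves no residual degrees of freedom")
    sigma = np.sqrt((resid ** 2).sum(axis=1) / d)

    sx = logcpm.mean(axis=1)
    sy = np.sqrt(sigma)
    trend = lowess(sy, sx, frac=span, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    tx, uniq = np.unique(tx, return_index=True)
    ty = ty[uniq]
    interp = np.interp(fitted, tx, ty)           # flat beyond the data range
    interp = np.maximum(interp, 1e-3)
    weights = interp ** -4

    idx, cols = pb.index, pb.columns
    return (pd.DataFrame(logcpm, index=idx, columns=cols),
            pd.DataFrame(weights, index=idx, columns=cols))


# ---------------------------------------------------------------------------
# empirical-Bayes moderated linear model
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match log s^2 to a scaled chi-square: returns (d0, s0^2)."""
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return d0, s02


def fit_moderated(logcpm: pd.DataFrame, weights: pd.DataFrame,
                  design: DesignSpec,
                  profile: SignificanceProfile = PROFILES["pseudobulk"],
                  prior_df: float | None = None) -> pd.DataFrame:
    """Weighted least squares per gene with empirical-Bayes variance shrinkage.

    ``prior_df`` overrides the estimated prior degrees of freedom: 0 recovers
    ordinary per-gene weighted t-tests, ``inf`` pools every gene onto the
    prior variance.
    """
    X, coef = design.matrix()
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is not full rank; contrast not estimable")
    d = n - p
    if d <= 0:
        raise ValueError("no residual degrees of freedom")

    Y = logcpm.to_numpy(dtype=np.float64)
    W = weights.to_numpy(dtype=np.float64)
    G = Y.shape[0]
    betas = np.empty(G)
    s2 = np.empty(G)
    unscaled = np.empty(G)
    for g in range(G):
        w = W[g]
        A = X.T @ (X * w[:, None])
        b = X.T @ (w * Y[g])
        Ainv = np.linalg.inv(A)
        beta = Ainv @ b
        r = Y[g] - X @ beta
        betas[g] = beta[coef]
        s2[g] = float(np.sum(w * r * r) / d)
        unscaled[g] = Ainv[coef, coef]

    if prior_df is None:
        d0, s02 = _fit_variance_prior(s2, d)
    elif prior_df == 0:
        d0, s02 = 0.0, 0.0
    elif np.isinf(prior_df):
        d0, s02 = np.inf, float(np.mean(s2))
    else:
        d0 = float(prior_df)
        _, s02 = _fit_variance_prior(s2, d)

    if np.isinf(d0):
        post_var = np.full(G, s02)
        df_total = np.inf
    else:
        post_var = (d0 * s02 + d * s2) / (d0 + d)
        df_total = d0 + d

    se = np.sqrt(post_var * unscaled)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, betas / se, 0.0)
    if np.isinf(df_total):
        p_raw = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p_raw = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    p_adj = multipletests(p_raw, method="fdr_bh")[1]

    cond = np.array(design.condition)
    mean_a = Y[:, cond == design.contrast[0]].mean(axis=1)
    mean_b = Y[:, cond == design.contrast[1]].mean(axis=1)
    table = pd.DataFrame({
        "gene": logcpm.index, "log2fc": betas,
        "p_raw": p_raw, "p_adj": p_adj,
        "pct_a": np.nan, "pct_b": np.nan,
        "mean_a": mean_a, "mean_b": mean_b,
        "t": tstat,
    })
    table["call"] = _calls(table, profile)
    return table


# ---------------------------------------------------------------------------
# paired bulk engine
# ---------------------------------------------------------------------------

def de_paired_bulk(bulk: pd.DataFrame, patient_labels, treatment_labels,
                   profile: SignificanceProfile = PROFILES["human"],
                   min_count: int = 5, min_samples: int = 2) -> pd.DataFrame:
    """Paired treated-vs-control DE with a patient blocking factor.

    Genes need at least ``min_count`` counts in at least ``min_samples``
    samples; the design is intercept + patient indicators + treatment, and
    the treatment coefficient is tested with the moderated model.
    """
    patients = tuple(str(x) for x in patient_labels)
    treatments = tuple(str(x) for x in treatment_labels)
    if not (len(patients) == len(treatments) == bulk.shape[1]):
        raise ValueError("labels must match the number of bulk samples")
    for pat in dict.fromkeys(patients):
        arms = {t for p, t in zip(patients, treatments) if p == pat}
        if arms != {"treated", "control"}:
            raise ValueError(f"patient {pat!r} is unpaired (arms seen: {sorted(arms)})")

    keep = (bulk.to_numpy() >= min_count).sum(axis=1) >= min_samples
    filtered = bulk.loc[keep]
    design = DesignSpec(condition=treatments, blocking=patients)
    factors = tmm_factors(filtered)
    logcpm, weights = precision_weighted_transform(filtered, factors, design)
    return fit_moderated(logcpm, weights, design, profile=profile)


# ---------------------------------------------------------------------------
# significance classification
# ---------------------------------------------------------------------------

def _calls(table: pd.DataFrame, profile: SignificanceProfile) -> pd.Series:
    p = table["p_adj"] if profile.use_fdr else table["p_raw"]
    sig = (p < profile.p_max) & p.notna()
    up = sig & (table["log2fc"] > profile.lfc_min)
    down = sig & (table["log2fc"] < -profile.lfc_min)
    call = pd.Series("ns", index=table.index, dtype=object)
    call[up] = "up"
    call[down] = "down"
    return call


def classify(table: pd.DataFrame,
             profile: SignificanceProfile) -> pd.DataFrame:
    """Collapse a DE table to a per-gene direction map (up / down / ns)."""
    out = pd.DataFrame({"gene": table["gene"],
                        "direction": _calls(table, profile),
                        "log2fc": table["log2fc"]})
    return out.reset_index(drop=True)
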