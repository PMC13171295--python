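"""Differential-expression engines against independent oracles."""

import itertools
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import txrescue as tx
from txrescue.diffexpr import _exact_rank_p, _fit_variance_prior
from conftest import make_adata


# ---------------------------------------------------------------------------
# lognormalize
# ---------------------------------------------------------------------------

def test_lognormalize_formula_and_zero_handling():
    counts = np.zeros((2, 3), dtype=int)
    counts[0] = [100, 4900, 5000]          # total 10,000
    adata = tx.lognormalize(make_adata(counts))
    X = np.asarray(adata.X.todense() if hasattr(adata.X, "todense") else adata.X)
    assert X[0, 0] == pytest.approx(np.log(101.0))
    assert (X[1] == 0).all()               # all-zero cell stays zero


def test_lognormalize_restores_scale_on_expm1():
    rng = np.random.default_rng(1)
    adata = tx.lognormalize(make_adata(rng.integers(0, 20, size=(5, 40))), scale=1e4)
    X = np.asarray(adata.X.todense() if hasattr(adata.X, "todense") else adata.X)
    np.testing.assert_allclose(np.expm1(X).sum(axis=1), 1e4, rtol=1e-10)


# ---------------------------------------------------------------------------
# rank-sum engine
# ---------------------------------------------------------------------------

def test_exact_rank_p_matches_enumeration():
    # 2 of the C(6,3)=20 assignments are as extreme (both tails)
    assert _exact_rank_p(np.array([10., 11., 12.]),
                         np.array([1., 2., 3.])) == pytest.approx(0.1)


def test_identical_groups_give_p_one_and_ns():
    rng = np.random.default_rng(0)
    base = rng.integers(0, 8, size=(4, 30))
    counts = np.vstack([base, base])
    obs = pd.DataFrame({"condition": ["a"] * 4 + ["b"] * 4},
                       index=[f"c{i}" for i in range(8)])
    adata = tx.lognormalize(make_adata(counts, obs=obs))
    table = tx.de_wilcoxon(adata, "a", "b", profile=tx.SignificanceProfile(
        lfc_min=0.0, min_pct=None))
    tested = table["p_raw"].notna()
    assert (table.loc[tested, "p_raw"] == 1.0).all()
    assert (table["call"] == "ns").all()


def test_exact_and_normal_approximation_agree_at_8v8():
    rng = np.random.default_rng(2)
    counts = rng.integers(0, 50, size=(16, 60))
    obs = pd.DataFrame({"condition": ["a"] * 8 + ["b"] * 8},
                       index=[f"c{i}" for i in range(16)])
    adata = tx.lognormalize(make_adata(counts, obs=obs))
    profile = tx.SignificanceProfile(lfc_min=0.0, min_pct=None)
    exact = tx.de_wilcoxon(adata, "a", "b", profile=profile, max_exact=8)
    approx = tx.de_wilcoxon(adata, "a", "b", profile=profile, max_exact=0)
    assert np.nanmax(np.abs(exact["p_raw"] - approx["p_raw"])) < 0.02


def test_min_pct_gates_testing_but_lfc_gates_calls():
    # strong gene failing the 0.58 fold-change bound stays ns
    table = pd.DataFrame({"gene": ["g"], "log2fc": [0.5], "p_raw": [1e-4],
                          "p_adj": [1e-3], "pct_a": [0.5], "pct_b": [0.5],
                          "mean_a": [1.0], "mean_b": [0.7]})
    out = tx.classify(table, tx.PROFILES["snrna"])
    assert out.loc[0, "direction"] == "ns"


def test_raw_p_uniform_on_continuous_null():
    rng = np.random.default_rng(7)
    n = 100
    X = rng.normal(size=(2 * n, 1000))
    obs = pd.DataFrame({"condition": ["a"] * n + ["b"] * n},
                       index=[f"c{i}" for i in range(2 * n)])
    adata = make_adata(np.zeros((2 * n, 1000), dtype=int), obs=obs)
    adata.X = X    # already on a continuous scale
    table = tx.de_wilcoxon(adata, "a", "b",
                           profile=tx.SignificanceProfile(lfc_min=0.0, min_pct=None))
    ks = stats.kstest(table["p_raw"], "uniform")
    assert ks.pvalue > 0.01
    # BH keeps the adjusted p monotone in the raw p
    srt = table.sort_values("p_raw")
    assert srt["p_adj"].is_monotonic_increasing


# ---------------------------------------------------------------------------
# pseudo-bulk construction and filtering
# ---------------------------------------------------------------------------

def test_pseudobulk_sums_and_preserves_order():
    counts = np.array([[3, 1], [1, 0], [5, 2]])
    obs = pd.DataFrame({"sample": ["s1", "s1", "s0"]},
                       index=["c0", "c1", "c2"])
    pb = tx.pseudobulk(make_adata(counts, genes=["gA", "gB"], obs=obs))
    assert list(pb.columns) == ["s1", "s0"]     # first-appearance order
    assert pb["s1"].tolist() == [4, 1]
    assert pb["s0"].tolist() == [5, 2]
    assert pb.to_numpy().sum() == counts.sum()


def test_filter_low_expression_worked_example():
    # 5 samples, libraries of 1,000 counts each; groups of size (3, 2) -> k = 2
    other = np.full((1, 5), 0)
    gene = np.array([[20, 20, 0, 0, 0]])
    filler = np.array([[980, 980, 1000, 1000, 1000]])
    pb = pd.DataFrame(np.vstack([gene, other, filler]),
                      index=["g_hit", "g_zero", "g_fill"],
                      columns=list("abcde"))
    design = tx.DesignSpec(condition=("treated", "treated", "control",
                                      "control", "control"))
    kept = tx.filter_low_expression(pb, design, min_count=10, min_total=15)
    # CPM cutoff = 10/1000*1e6 = 10,000; the hit reaches 20,000 CPM twice
    assert "g_hit" in kept.index and "g_zero" not in kept.index
    # raising min_count past the gene's CPM removes it (monotone)
    kept25 = tx.filter_low_expression(pb, design, min_count=25, min_total=15)
    assert "g_hit" not in kept25.index
    assert set(kept25.index) <= set(kept.index)


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def test_tmm_identical_and_scaled_samples_get_unit_factors():
    rng = np.random.default_rng(3)
    a = rng.integers(1, 200, size=50).astype(float)
    pb = pd.DataFrame({"a": a, "b": a, "c": 3 * a})
    f = tx.tmm_factors(pb)
    np.testing.assert_allclose(f.to_numpy(), 1.0, atol=1e-9)


def _brute_tmm_pair(counts, j, ref, trim_m=0.3, trim_a=0.05):
    """Independent two-sample TMM evaluation by explicit sorting."""
    lib = counts.sum(axis=0)
    obs_j, obs_r = counts[:, j] / lib[j], counts[:, ref] / lib[ref]
    fin = (counts[:, j] > 0) & (counts[:, ref] > 0)
    M = np.log2(obs_j[fin] / obs_r[fin])
    A = 0.5 * np.log2(obs_j[fin] * obs_r[fin])
    w = ((lib[j] - counts[fin, j]) / (lib[j] * counts[fin, j])
         + (lib[ref] - counts[fin, ref]) / (lib[ref] * counts[fin, ref]))
    n = M.size
    lo_m = int(np.floor(n * trim_m)) + 1
    lo_a = int(np.floor(n * trim_a)) + 1
    rm = stats.rankdata(M)
    ra = stats.rankdata(A)
    keep = (rm >= lo_m) & (rm <= n + 1 - lo_m) & (ra >= lo_a) & (ra <= n + 1 - lo_a)
    return 2.0 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))


def test_tmm_matches_brute_force_trimmed_weighted_mean():
    rng = np.random.default_rng(4)
    counts = rng.integers(5, 500, size=(10, 2)).astype(float)
    counts[:2, 1] *= 8           # two inflated genes in sample B
    pb = pd.DataFrame(counts, columns=["A", "B"])
    f = tx.tmm_factors(pb)
    lib = counts.sum(axis=0)
    f75 = np.quantile(counts, 0.75, axis=0) / lib
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    j = 1 - ref
    raw = _brute_tmm_pair(counts, j, ref)
    expected = {j: raw / np.sqrt(raw), ref: 1.0 / np.sqrt(raw)}  # geo-mean 1
    np.testing.assert_allclose(f.to_numpy(), [expected[0], expected[1]],
                               rtol=1e-12)


def test_tmm_matches_edger_reference(tmp_path):
    rng = np.random.default_rng(5)
    counts = rng.integers(1, 1000, size=(200, 4))
    counts[:10, 2] *= 5
    pb = pd.DataFrame(counts.astype(float), columns=list("abcd"))
    ours = tx.tmm_factors(pb)
    csv = tmp_path / "counts.csv"
    pb.to_csv(csv, index=False)
    script = textwrap.dedent(f"""
        suppressMessages(library(edgeR))
        counts <- as.matrix(read.csv("{csv}"))
        f <- calcNormFactors(DGEList(counts=counts), method="TMM")
        cat(sprintf("%.12f", f$samples$norm.factors), sep="\\n")
    """)
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, check=True)
    reference = np.array([float(x) for x in out.stdout.split()])
    np.testing.assert_allclose(ours.to_numpy(), reference, rtol=1e-8)


def test_tmm_geometric_mean_is_one(small_cohort):
    pb = tx.pseudobulk(small_cohort.snrna)
    f = tx.tmm_factors(pb)
    assert abs(np.log(f).mean()) < 1e-12


# ---------------------------------------------------------------------------
# precision weights
# ---------------------------------------------------------------------------

def _toy_design(n_a, n_b):
    return tx.DesignSpec(condition=("treated",) * n_a + ("control",) * n_b)


def test_weights_positive_and_flat_under_homoskedastic_data():
    rng = np.random.default_rng(6)
    n, G = 20, 400
    mu = rng.uniform(5, 12, size=G)
    logc = mu[:, None] + rng.normal(0, 0.25, size=(G, n))
    counts = pd.DataFrame(np.rint(2.0 ** logc),
                          index=[f"g{i}" for i in range(G)],
                          columns=[f"s{i}" for i in range(n)])
    design = _toy_design(10, 10)
    factors = tx.tmm_factors(counts)
    logcpm, weights = tx.precision_weighted_transform(counts, factors, design)
    w = weights.to_numpy()
    assert (w > 0).all()
    assert w.std() / w.mean() < 0.10


def test_transform_handles_zero_counts_finitely():
    pb = pd.DataFrame({"a": [0, 100, 50], "b": [0, 90, 60],
                       "c": [1, 80, 70], "d": [2, 110, 40]},
                      index=["g0", "g1", "g2"]).astype(float)
    logcpm, weights = tx.precision_weighted_transform(
        pb, tx.tmm_factors(pb), _toy_design(2, 2))
    assert np.isfinite(logcpm.to_numpy()).all()
    assert (weights.to_numpy() > 0).all()


# ---------------------------------------------------------------------------
# moderated linear model
# ---------------------------------------------------------------------------

def _classical_weighted_fit(logcpm, weights, design):
    """Independent per-gene WLS: returns (t, p, beta, s2, unscaled_var)."""
    X, coef = design.matrix()
    d = X.shape[0] - X.shape[1]
    out = {k: [] for k in ("t", "p", "beta", "s2", "v")}
    for g in range(logcpm.shape[0]):
        w = weights.iloc[g].to_numpy()
        y = logcpm.iloc[g].to_numpy()
        A = X.T @ (X * w[:, None])
        Ainv = np.linalg.inv(A)
        beta = Ainv @ (X.T @ (w * y))
        r = y - X @ beta
        s2 = np.sum(w * r * r) / d
        se = np.sqrt(s2 * Ainv[coef, coef])
        out["t"].append(beta[coef] / se)
        out["p"].append(2 * stats.t.sf(abs(beta[coef] / se), d))
        out["beta"].append(beta[coef])
        out["s2"].append(s2)
        out["v"].append(Ainv[coef, coef])
    return {k: np.array(v) for k, v in out.items()}


@pytest.fixture(scope="module")
def moderated_fixture():
    rng = np.random.default_rng(8)
    counts = pd.DataFrame(rng.integers(20, 2000, size=(100, 8)).astype(float),
                          index=[f"g{i}" for i in range(100)],
                          columns=[f"s{i}" for i in range(8)])
    design = _toy_design(4, 4)
    factors = tx.tmm_factors(counts)
    logcpm, weights = tx.precision_weighted_transform(counts, factors, design)
    return logcpm, weights, design


def test_zero_prior_df_reduces_to_classical_t(moderated_fixture):
    logcpm, weights, design = moderated_fixture
    table = tx.fit_moderated(logcpm, weights, design, prior_df=0)
    ref = _classical_weighted_fit(logcpm, weights, design)
    assert np.max(np.abs(table["t"].to_numpy() - ref["t"])) < 1e-8
    np.testing.assert_allclose(table["p_raw"].to_numpy(), ref["p"], atol=1e-10)


def test_infinite_prior_df_pools_all_variances(moderated_fixture):
    logcpm, weights, design = moderated_fixture
    table = tx.fit_moderated(logcpm, weights, design, prior_df=np.inf)
    ref = _classical_weighted_fit(logcpm, weights, design)
    pooled = ref["s2"].mean()
    expected_t = ref["beta"] / np.sqrt(pooled * ref["v"])
    np.testing.assert_allclose(table["t"].to_numpy(), expected_t, rtol=1e-10)


def test_variance_prior_moment_matching_recovers_known_prior():
    rng = np.random.default_rng(9)
    d, d0, s02 = 4, 8.0, 2.0
    # sample gene variances from the scaled inverse-chi-square hierarchy
    true_var = s02 * d0 / rng.chisquare(d0, size=20000)
    s2 = true_var * rng.chisquare(d, size=20000) / d
    d0_hat, s02_hat = _fit_variance_prior(s2, d)
    assert abs(d0_hat - d0) / d0 < 0.15
    assert abs(s02_hat - s02) / s02 < 0.05


def test_moderated_null_type_one_error():
    rng = np.random.default_rng(10)
    mu = rng.uniform(50, 500, size=500)
    counts = pd.DataFrame(
        rng.negative_binomial(10, 10 / (10 + mu)[:, None], size=(500, 10)).astype(float),
        index=[f"g{i}" for i in range(500)], columns=[f"s{i}" for i in range(10)])
    design = _toy_design(5, 5)
    filt = tx.filter_low_expression(counts, design)
    factors = tx.tmm_factors(filt)
    logcpm, weights = tx.precision_weighted_transform(filt, factors, design)
    table = tx.fit_moderated(logcpm, weights, design)
    frac = (table["p_raw"] < 0.05).mean()
    assert 0.03 <= frac <= 0.07


# ---------------------------------------------------------------------------
# paired bulk engine
# ---------------------------------------------------------------------------

def _paired_labels(n_patients):
    patients = [f"P{i}" for i in range(n_patients) for _ in range(2)]
    treatments = ["control", "treated"] * n_patients
    return patients, treatments


def test_paired_bulk_count_filter():
    patients, treatments = _paired_labels(3)
    counts = pd.DataFrame(
        {f"s{i}": [4, 5, 1000] for i in range(6)}, index=["g_low", "g_edge", "g_fill"])
    table = tx.de_paired_bulk(counts, patients, treatments)
    assert "g_low" not in set(table["gene"])     # never reaches 5 counts
    assert "g_edge" in set(table["gene"])        # >= 5 in >= 2 samples


def test_blocking_absorbs_patient_intercepts():
    rng = np.random.default_rng(11)
    G = 300
    base = rng.uniform(50, 2000, size=G)
    cols = {}
    patients, treatments = _paired_labels(3)
    for i, (pat, _) in enumerate(zip(patients, treatments)):
        pat_effect = {"P0": 0.3, "P1": 1.0, "P2": 3.0}[pat]
        lam = base * pat_effect
        cols[f"s{i}"] = rng.poisson(lam * (1e6 / lam.sum()))
    counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(G)]).astype(float)
    table = tx.de_paired_bulk(counts, patients, treatments)
    assert table["log2fc"].abs().mean() < 0.1
    assert (table["call"] == "ns").mean() > 0.95


def test_paired_bulk_recovers_planted_fold_change():
    rng = np.random.default_rng(12)
    G = 300
    base = rng.uniform(100, 2000, size=G)
    patients, treatments = _paired_labels(3)
    cols = {}
    for i, (pat, trt) in enumerate(zip(patients, treatments)):
        lam = base.copy()
        if trt == "treated":
            lam[:10] *= 4.0                     # planted 4-fold increase
        cols[f"s{i}"] = rng.poisson(lam)
    counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(G)]).astype(float)
    table = tx.de_paired_bulk(counts, patients, treatments).set_index("gene")
    assert (table.loc[[f"g{i}" for i in range(10)], "call"] == "up").all()


def test_unpaired_patient_is_rejected_by_name():
    counts = pd.DataFrame(np.ones((5, 4)) * 100, columns=list("abcd"))
    with pytest.raises(ValueError, match="P1"):
        tx.de_paired_bulk(counts, ["P0", "P0", "P1", "P1"],
                          ["control", "treated", "treated", "treated"])


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("lfc,p_raw,p_adj,profile,expected", [
    (1.2, 0.001, 0.01, "pseudobulk", "up"),
    (-1.2, 0.04, 0.2, "human", "down"),       # raw-p criterion
    (-1.2, 0.04, 0.2, "pseudobulk", "ns"),    # FDR criterion fails
    (1.2, 0.001, 0.05, "pseudobulk", "ns"),   # p exactly at threshold
    (1.0, 0.001, 0.001, "pseudobulk", "ns"),  # lfc exactly at threshold
])
def test_classification_thresholds_are_strict(lfc, p_raw, p_adj, profile, expected):
    table = pd.DataFrame({"gene": ["g"], "log2fc": [lfc], "p_raw": [p_raw],
                          "p_adj": [p_adj]})
    out = tx.classify(table, tx.PROFILES[profile])
    assert out.loc[0, "direction"] == expected
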