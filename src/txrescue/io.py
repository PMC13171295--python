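"""File input/output: 10x-style Matrix Market layouts and TSV tables.

Counts travel as Matrix Market coordinate triplets (1-based indices, genes
as rows, barcodes as columns) beside ``genes.tsv``/``barcodes.tsv`` and a
cell-metadata TSV; bulk counts and every derived table are TSV with explicit
headers.  Floats are serialized at 10 significant digits so identical runs
produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import anndata as ad
from scipy import io as scio
from scipy import sparse

from .simdata import SyntheticCohort

FLOAT_FMT = "%.10g"


def _validate_mm_1based(path: Path) -> None:
    """Reject coordinate files with 0-based (or otherwise invalid) indices."""
    with open(path) as fh:
        header = fh.readline()
        if "coordinate" not in header:
            return          # array format has no indices to validate
        line = fh.readline()
        while line.startswith("%"):
            line = fh.readline()
        n_rows, n_cols, _ = (int(x) for x in line.split())
        pos = fh.tell()
        if not fh.readline():
            return                       # no entries to validate
        fh.seek(pos)
        idx = pd.read_csv(fh, sep=r"\s+", header=None, usecols=[0, 1],
                          dtype=np.int64)
    rmin, cmin = idx[0].min(), idx[1].min()
    if rmin < 1 or cmin < 1:
        raise ValueError(
            f"{path}: Matrix Market triplets must use 1-based indices "
            f"(found row index {rmin}, column index {cmin})")
    if idx[0].max() > n_rows or idx[1].max() > n_cols:
        raise ValueError(f"{path}: triplet indices exceed the declared "
                         f"{n_rows} x {n_cols} dimensions")


def read_counts_10x(directory) -> ad.AnnData:
    """Load matrix.mtx + genes.tsv + barcodes.tsv (+ cell_metadata.tsv).

    The matrix is stored genes x barcodes; the returned AnnData is cells x
    genes with integer counts preserved.
    """
    d = Path(directory)
    mtx = d / "matrix.mtx"
    _validate_mm_1based(mtx)
    X = sparse.csr_matrix(scio.mmread(mtx)).T.astype(np.int64)
    genes = pd.read_csv(d / "genes.tsv", sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    if X.shape != (len(barcodes), len(genes)):
        raise ValueError(
            f"{mtx}: matrix is {X.shape[1]} genes x {X.shape[0]} barcodes but "
            f"genes.tsv lists {len(genes)} genes and barcodes.tsv "
            f"{len(barcodes)} barcodes")
    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    meta_path = d / "cell_metadata.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        obs = meta.loc[barcodes]
    return ad.AnnData(X=X, obs=obs,
                      var=pd.DataFrame(index=pd.Index(genes, name="gene")))


def write_counts_10x(adata: ad.AnnData, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    X = adata.X
    mat = (X.T if sparse.issparse(X) else sparse.csr_matrix(np.asarray(X)).T)
    scio.mmwrite(d / "matrix.mtx", sparse.coo_matrix(mat).astype(np.int64))
    pd.Series(list(adata.var_names)).to_csv(d / "genes.tsv", sep="\t",
                                            header=False, index=False)
    pd.Series(list(adata.obs_names)).to_csv(d / "barcodes.tsv", sep="\t",
                                            header=False, index=False)
    if adata.obs.shape[1]:
        adata.obs.to_csv(d / "cell_metadata.tsv", sep="\t",
                         float_format=FLOAT_FMT)


def read_bulk_tsv(counts_path, meta_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    if not set(counts.columns) == set(meta.index):
        raise ValueError(f"{counts_path}: sample columns do not match "
                         f"{meta_path} rows")
    return counts, meta.loc[counts.columns]


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Persist a synthetic cohort in the package's on-disk layout."""
    out = Path(outdir)
    write_counts_10x(cohort.snrna, out / "snrna")
    write_table(cohort.bulk_counts, out / "bulk_counts.tsv", index=True)
    write_table(cohort.bulk_meta, out / "bulk_metadata.tsv", index=True)
    write_table(cohort.cancer_signature, out / "cancer_signature.tsv")
    write_table(cohort.ortholog_map, out / "ortholog_map.tsv")
    write_table(cohort.lr_table, out / "lr_pairs.tsv")
    (out / "truth.json").write_text(cohort.truth.to_json())


def read_direction_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "direction"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns gene, direction")
    return df
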