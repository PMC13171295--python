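"""Hypergeometric over-representation analysis and cell-type composition.

ORA tests a query gene list against named gene sets within a background
universe: p = P(X >= k) for a hypergeometric draw of n query genes from a
universe of M containing K set members.  BH adjustment runs within each
set-category label separately (mirroring per-ontology testing).  Composition
summarizes per-sample and per-condition cell-type fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(members) for name, members in self.sets.items()}


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (set name, description, tab-separated members)."""
    sets, desc = {}, {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
            desc[parts[0]] = parts[1]
    return GeneSetCollection(sets=sets, descriptions=desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def ora_hypergeometric(query, universe, collection: GeneSetCollection,
                       min_overlap: int = 1) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each set.

    Query genes outside the universe are dropped with a warning; set members
    are restricted to the universe.  Fold enrichment is (k/n)/(K/M).
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    query = frozenset(query)
    outside = query - universe
    if outside:
        log.warning("ora: dropping %d query gene(s) outside the universe",
                    len(outside))
    query &= universe
    M, n = len(universe), len(query)

    rows = []
    for name, members in collection.sets.items():
        K = len(members & universe)
        k = len(members & query)
        if k < min_overlap or K == 0:
            continue
        p = float(hypergeom.sf(k - 1, M, K, n))
        fold = (k / n) / (K / M) if n > 0 else np.nan
        rows.append({"set": name, "category": collection.categories.get(name, ""),
                     "k": k, "K": K, "n": n, "M": M, "p": min(p, 1.0),
                     "fold_enrichment": fold})
    table = pd.DataFrame(rows, columns=["set", "category", "k", "K", "n", "M",
                                        "p", "fold_enrichment"])
    if table.empty:
        table["q"] = pd.Series(dtype=float)
        return table
    q = np.empty(len(table))
    for _, idx in table.groupby("category").groups.items():
        q[table.index.get_indexer(idx)] = multipletests(
            table.loc[idx, "p"], method="fdr_bh")[1]
    table["q"] = q
    return table.sort_values(["p", "set"], ignore_index=True)


def composition(labels: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell-type composition per sample plus pooled per-condition fractions.

    ``labels`` needs columns sample, condition, cell_type (one row per cell).
    Cell types absent from a sample are reported with fraction 0.
    """
    required = {"sample", "condition", "cell_type"}
    if not required <= set(labels.columns):
        raise ValueError(f"labels must have columns {sorted(required)}")
    all_types = sorted(labels["cell_type"].unique())

    rows = []
    for (cond, sample), grp in labels.groupby(["condition", "sample"],
                                              observed=True, sort=True):
        counts = grp["cell_type"].value_counts()
        total = len(grp)
        for ct in all_types:
            n = int(counts.get(ct, 0))
            rows.append({"condition": cond, "sample": sample, "cell_type": ct,
                         "n_cells": n, "fraction": n / total})
    per_sample = pd.DataFrame(rows)

    pooled_rows = []
    for cond, grp in labels.groupby("condition", observed=True, sort=True):
        counts = grp["cell_type"].value_counts()
        total = len(grp)
        for ct in all_types:
            n = int(counts.get(ct, 0))
            pooled_rows.append({"condition": cond, "cell_type": ct,
                                "n_cells": n, "fraction": n / total})
    return per_sample, pd.DataFrame(pooled_rows)
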