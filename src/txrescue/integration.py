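"""Cross-species joining, rescue statistics and conserved-target isolation.

Direction maps from different species are joined through a one-to-one
ortholog map (optionally restricted to protein-coding genes) onto a shared
universe keyed by canonical species-A identifiers.  Within that universe the
module computes the "rescue" fraction — the share of treatment-responsive
genes whose treatment direction is the strict opposite of their cancer
direction — and the conserved sets: genes cancer-up and treatment-down (or
the converse) in every supplied analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger(__name__)

DIRECTIONS = ("up", "down", "ns")


def _as_direction_series(table) -> pd.Series:
    """Accept a direction DataFrame (gene, direction) or Series keyed by gene."""
    if isinstance(table, pd.Series):
        s = table
    else:
        if table["gene"].duplicated().any():
            dup = table.loc[table["gene"].duplicated(), "gene"].iloc[0]
            raise ValueError(f"duplicate gene {dup!r} within a direction table")
        s = table.set_index("gene")["direction"]
    if s.index.duplicated().any():
        dup = s.index[s.index.duplicated()][0]
        raise ValueError(f"duplicate gene {dup!r} within a direction table")
    bad = set(s.unique()) - set(DIRECTIONS)
    if bad:
        raise ValueError(f"unknown direction labels {sorted(bad)}")
    return s


@dataclass
class IntegrationResult:
    shared_universe: frozenset[str]
    responsive: frozenset[str]
    reversed_genes: frozenset[str]
    rescue_fraction: float | None
    conserved_down: frozenset[str]
    conserved_up: frozenset[str]
    directions: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not self.reversed_genes <= self.responsive <= self.shared_universe:
            raise ValueError("reversed ⊆ responsive ⊆ shared_universe violated")


def join_orthologs(tables: dict[str, object], ortholog_map: pd.DataFrame,
                   species_b: tuple[str, ...] = (),
                   protein_coding_only: bool = False) -> pd.DataFrame:
    """Join per-species direction maps onto a canonical (species-A) universe.

    ``tables`` maps analysis name -> direction table; analyses named in
    ``species_b`` are keyed by species-B identifiers and are translated
    through the one-to-one map (genes mapped non-uniquely are excluded).
    The output holds one direction column per analysis, indexed by the genes
    present in *all* tables after mapping.
    """
    m = ortholog_map.copy()
    uniq = (~m["gene_human"].duplicated(keep=False)
            & ~m["gene_mouse"].duplicated(keep=False))
    m = m.loc[uniq]
    if protein_coding_only and "protein_coding" in m.columns:
        m = m.loc[m["protein_coding"].astype(bool)]
    b_to_a = dict(zip(m["gene_mouse"], m["gene_human"]))

    mapped: dict[str, pd.Series] = {}
    for name, table in tables.items():
        s = _as_direction_series(table)
        if name in species_b:
            s = s[s.index.isin(b_to_a)]
            s.index = [b_to_a[g] for g in s.index]
        else:
            s = s[s.index.isin(set(m["gene_human"]))]
        mapped[name] = s

    universe = None
    for s in mapped.values():
        genes = set(s.index)
        universe = genes if universe is None else universe & genes
    universe = sorted(universe or set())
    return pd.DataFrame({name: s.loc[universe] for name, s in mapped.items()},
                        index=pd.Index(universe, name="gene"))


def rescue_stats(treatment_dirs, cancer_dirs,
                 universe=None) -> tuple[int, int, float | None]:
    """(n_responsive, n_reversed, fraction) of treatment-reversed genes.

    Responsive genes have a non-ns treatment direction; reversed genes are
    responsive genes whose cancer direction is the strict opposite (cancer ns
    never counts).  The fraction is ``None`` (undefined) when nothing is
    responsive.
    """
    t = _as_direction_series(treatment_dirs)
    c = _as_direction_series(cancer_dirs)
    if universe is not None:
        universe = list(universe)
        t = t.reindex(universe, fill_value="ns")
        c = c.reindex(universe, fill_value="ns")
    else:
        common = t.index.intersection(c.index)
        t, c = t.loc[common], c.loc[common]
    responsive = t.isin(("up", "down"))
    reversed_mask = responsive & (
        ((t == "up") & (c == "down")) | ((t == "down") & (c == "up")))
    n_resp = int(responsive.sum())
    n_rev = int(reversed_mask.sum())
    if n_resp == 0:
        log.warning("rescue_stats: no responsive genes; fraction undefined")
        return 0, 0, None
    return n_resp, n_rev, n_rev / n_resp


def conserved_intersection(cancer_dirs, analyses: dict[str, object],
                           universe=None) -> tuple[frozenset[str], frozenset[str]]:
    """Genes whose treatment direction opposes cancer in *every* analysis.

    Returns (conserved_down, conserved_up): cancer-up genes down in all
    analyses, and cancer-down genes up in all analyses.
    """
    if not analyses:
        raise ValueError("at least one analysis is required")
    c = _as_direction_series(cancer_dirs)
    if universe is not None:
        universe = list(universe)
        c = c.reindex(universe, fill_value="ns")
    down_all, up_all = None, None
    for table in analyses.values():
        s = _as_direction_series(table)
        if universe is not None:
            s = s.reindex(universe, fill_value="ns")
        down = set(s.index[s == "down"])
        up = set(s.index[s == "up"])
        down_all = down if down_all is None else down_all & down
        up_all = up if up_all is None else up_all & up
    cancer_up = set(c.index[c == "up"])
    cancer_down = set(c.index[c == "down"])
    return (frozenset(cancer_up & down_all), frozenset(cancer_down & up_all))


def upset_counts(sets: dict[str, set]) -> pd.DataFrame:
    """Cardinality of every non-empty exclusive intersection region.

    Rows carry one boolean membership column per input set plus the count of
    elements exactly in that membership pattern; regions are disjoint and
    cover the union.
    """
    if len(sets) > 12:
        raise ValueError("upset_counts supports at most 12 sets")
    names = list(sets)
    region_counts: dict[tuple[bool, ...], int] = {}
    union = set().union(*sets.values()) if sets else set()
    for el in union:
        pattern = tuple(el in sets[n] for n in names)
        region_counts[pattern] = region_counts.get(pattern, 0) + 1
    rows = [dict(zip(names, pattern), count=count)
            for pattern, count in region_counts.items()]
    out = pd.DataFrame(rows, columns=[*names, "count"])
    return out.sort_values("count", ascending=False, ignore_index=True)


def cross_species_concordance(dirs_a, dirs_b,
                              universe=None) -> tuple[int, int, list[str], list[str]]:
    """Count genes called in the same direction in both species."""
    a = _as_direction_series(dirs_a)
    b = _as_direction_series(dirs_b)
    if universe is not None:
        universe = list(universe)
        a = a.reindex(universe, fill_value="ns")
        b = b.reindex(universe, fill_value="ns")
    else:
        common = a.index.intersection(b.index)
        a, b = a.loc[common], b.loc[common]
    both_up = sorted(a.index[(a == "up") & (b == "up")])
    both_down = sorted(a.index[(a == "down") & (b == "down")])
    return len(both_up), len(both_down), both_up, both_down


def integrate(cancer_dirs, analyses: dict[str, object],
              ortholog_map: pd.DataFrame, species_b: tuple[str, ...],
              protein_coding_only: bool = False,
              responsive_analyses: tuple[str, ...] | None = None) -> IntegrationResult:
    """End-to-end integration: join, rescue fraction, conserved sets.

    The rescue denominator uses the union of calls across
    ``responsive_analyses`` (default: all supplied analyses); conflicting
    directions between analyses collapse to ns.
    """
    tables = {"cancer": cancer_dirs, **analyses}
    joined = join_orthologs(tables, ortholog_map,
                            species_b=species_b,
                            protein_coding_only=protein_coding_only)
    universe = list(joined.index)
    use = responsive_analyses if responsive_analyses is not None else tuple(analyses)

    # union direction over the selected analyses; conflicts -> ns
    union_dir = pd.Series("ns", index=joined.index, dtype=object)
    for name in use:
        s = joined[name]
        called = s.isin(("up", "down"))
        conflict = called & union_dir.isin(("up", "down")) & (union_dir != s)
        union_dir[called] = s[called]
        union_dir[conflict] = "ns"

    n_resp, n_rev, frac = rescue_stats(union_dir, joined["cancer"], universe)
    responsive = frozenset(union_dir.index[union_dir.isin(("up", "down"))])
    rev = frozenset(
        union_dir.index[((union_dir == "up") & (joined["cancer"] == "down"))
                        | ((union_dir == "down") & (joined["cancer"] == "up"))])
    down, up = conserved_intersection(
        joined["cancer"], {n: joined[n] for n in analyses}, universe)
    return IntegrationResult(
        shared_universe=frozenset(universe), responsive=responsive,
        reversed_genes=rev, rescue_fraction=frac,
        conserved_down=down, conserved_up=up, directions=joined)
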