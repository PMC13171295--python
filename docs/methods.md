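# Methods

This note documents the statistical models behind `txrescue`, the
parameters that matter, the choices made where the design was genuinely
open, and what the synthetic cohort does and does not emulate.

## Synthetic cohort model

The generator emulates a three-part study design: a single-nucleus RNA-seq
arm (3 untreated + 2 treated mouse samples, 1,500 cells and 2,000 genes per
sample by default), a paired bulk arm (3 patients, one treated and one
untreated sample each, ~2×10⁶ reads per sample), and a population-level
cancer signature over the human gene universe.

**Counts.** Every count is negative binomial with mean
`library size × gene proportion × multipliers` and per-gene size 1/φ_g,
with dispersions φ_g log-normal around a configurable scale (0.3 for
single-nucleus, 0.05 for bulk) — the standard RNA-seq noise model. Gene
proportions come from a log-normal abundance law (log-sd 1.2); per-cell
library sizes are log-normal (median ≈ 5,000 counts, log-sd 0.35).

**Planted structure.**

- *Cell types*: 5 types with mildly uneven frequencies; each type has 20
  marker genes multiplied by 8.
- *Mitochondrial / damaged cells*: the first 1% of mouse genes carry an
  `mt-` prefix; healthy cells allocate 1.5% of their library to them,
  a 4% "damaged" subpopulation allocates 15%, so the 5% QC cut removes a
  known cell set.
- *Cancer signature*: 150 cancer-up and 150 cancer-down genes with planted
  directions, |log2FC| ≥ 1.5 and small adjusted p.
- *Treatment effects*: per species, 40 "rescued" genes (direction opposite
  their cancer direction) plus 60 treatment-responsive genes with a neutral
  cancer direction, all at |log2FC| = 2. The mouse and human rescued sets
  overlap in exactly one cancer-up gene — the planted conserved target.
  Planted genes are assigned abundances in the 55th–90th percentile so that
  recovery is limited by the measurement model rather than by dropout.
  Treatment multipliers apply across all cell types by default
  (`treated_celltypes` restricts them); a planted effect confined to one of
  five types would dilute below the pseudo-bulk |log2FC| > 1 call threshold
  by construction, which is a different experiment than the one the
  recovery analyses assume.
- *Paired bulk*: per-patient, per-gene log-normal intercepts (log-sd 0.3)
  are drawn once and shared by both members of a pair, giving the blocking
  factor something real to absorb.
- *Ligand-receptor channels*: each configured pair appends dedicated
  ligand/receptor genes whose expression is concentrated in the designated
  sender/receiver cell types and near zero elsewhere.
- *Orthologs*: mouse and human gene namespaces are disjoint and linked only
  by an explicit one-to-one map covering 80% of non-mitochondrial genes;
  10% of unplanted mapped genes are flagged non-protein-coding. This forces
  the integration stage to use the map rather than any name convention.

All randomness flows from a single seed through named `SeedSequence`
substreams, so identical configurations are byte-identical on disk.

**What the generator does not emulate**: doublets, ambient RNA, batch
effects beyond patient blocking, cell-type-specific dispersion, zero
inflation beyond the NB, spatial structure, or ortholog errors. Passing
recovery tests therefore demonstrates that the pipeline's statistics behave
as specified under a clean NB world — not that they are robust to every
artifact of real single-cell data.

## Quality control

Cells are kept when detected genes lie strictly between 200 and 5,000 and
the mitochondrial percentage is strictly below 5; all comparisons are
strict, mirroring the usual "greater than / less than" phrasing, so a cell
at exactly 5.0% mito is removed. The gene filter (expressed in ≥ 3 nuclei,
count > 0) runs *after* cell filtering and counts kept cells only; the
order is not dictated by the underlying protocol description, and
cells-first was chosen because the gene filter's intent is to drop genes
unsupported by the retained population. Removal reasons are attributed
first-match in the order min-genes, max-genes, mito, so the per-reason
tallies sum exactly to the removed-cell count.

## Differential expression

**Normalization.** `lognormalize` computes ln(1 + count/total × 10⁴) per
cell; all-zero cells map to zeros.

**Single-cell engine.** Two-sided Wilcoxon rank-sum per gene. When both
groups have ≤ 8 cells the p-value is computed by exact enumeration of all
C(n, n_a) rank assignments using mid-ranks (full ties give p = 1); larger
groups use the tie-corrected normal approximation with continuity
correction, implemented directly on a shared rank matrix (the statistic is
identical to `scipy.stats.mannwhitneyu(method="asymptotic")`, verified in
the tests, but avoids its broadcasting copies). Fold change is computed on
the de-logged scale with a pseudocount of 1,
log2((mean expm1 + 1)_a / (mean expm1 + 1)_b), matching the conventional
definition and avoiding division by zero. A gene is testable when expressed
in more than `min_pct` (default 10%) of cells in *at least one* group — the
permissive reading, which tests more genes; untestable genes carry NaN
p-values and call "ns". BH runs across tested genes only, within each DE
run.

**Pseudo-bulk engine.** Counts are summed per sample (first-appearance
column order), then filtered: a gene is kept when its CPM reaches the CPM
equivalent of 10 counts in the median library in at least k samples
(k = smallest condition group) and its total count is ≥ 15 — mirroring the
published description of the standard `filterByExpr` defaults, whose exact
parameters the underlying protocol does not state.

**TMM.** The reference sample is the one whose 75th-percentile CPM is
closest to the mean of those percentiles. Per sample, log2 ratios M against
the reference (over genes nonzero in both) are trimmed two-sided — 30% on M
and 5% on mean abundance A — and averaged with inverse asymptotic binomial
variance weights (N−x)/(Nx) + (N_r−r)/(N_r r); factors are rescaled to
geometric mean 1. The implementation reproduces edgeR's `calcNormFactors`
to 8+ digits on random fixtures (cross-checked against edgeR via Rscript in
the test suite).

**Precision weights.** logCPM = log2((count + 0.5)/(lib × factor + 1) × 10⁶);
gene-wise least squares under the design gives residual standard deviations
whose square roots are lowess-smoothed (span 0.5) against mean logCPM. Each
observation's weight is trend⁻⁴ at its fitted value; the trend is
interpolated flat beyond the data range and clamped at 10⁻³ so weights stay
finite and strictly positive.

**Moderated t.** Per-gene weighted least squares; residual variances s²
with d degrees of freedom are shrunk toward a prior via
s̃² = (d₀s₀² + d s²)/(d₀ + d), with (d₀, s₀²) estimated by moment-matching
log s² to a scaled chi-square (trigamma inversion by Newton iteration);
t = β̂/(s̃√v) on d₀ + d degrees of freedom. With d₀ = 0 the test reduces
exactly to the ordinary per-gene weighted t-test (oracle-checked to 1e-8);
with d₀ = ∞ every gene shares the pooled variance.

**Paired bulk engine.** The underlying study used a paired
negative-binomial Wald test; this package deliberately substitutes the same
precision-weighted moderated linear model used for pseudo-bulk, with
patient indicators as the blocking factor, keeping one well-specified
engine and honoring the published thresholds (raw p < 0.05, |log2FC| > 1).
The |log2FC| threshold is treated as absolute — the corresponding volcano
plots show called down-regulated genes, so the one-sided reading is
untenable. Gene filter: ≥ 5 counts in ≥ 2 samples.

**Significance profiles.** Four preset threshold sets: single-nucleus
(|log2FC| > 0.58, FDR < 0.05, > 10% expressed), pseudo-bulk (|log2FC| > 1,
FDR < 0.05), human bulk (|log2FC| > 1, raw p < 0.05), population signature
(|log2FC| > 1, FDR < 0.05). All comparisons strict.

## Integration

Direction tables are joined through the one-to-one ortholog map (rows
non-unique in either column are dropped; optional protein-coding
restriction) onto a universe of genes present in all tables, keyed by
canonical species-A (human) identifiers. "Responsive" = non-ns treatment
direction; "reversed" = responsive with the strictly opposite cancer
direction (cancer-ns genes are never reversed — reversal requires a defined
reference direction); the rescue fraction is reversed/responsive and is
reported as undefined, not 0, when nothing responds. For the mouse rescue
denominator the calls of the single-nucleus and pseudo-bulk tables are
combined by union (conflicting directions collapse to ns) — the published
mouse denominator is not uniquely attributable to one table, and the union
is the configurable default (`responsive_analyses`). The source text's
mouse rescue line is internally inconsistent (1,126/3,463 ≈ 32.5%, printed
as 35.4%); this package reports exact fractions and does not attempt to
reproduce that number. Conserved sets intersect all supplied analyses:
conserved-down = cancer-up ∩ treatment-down everywhere, and conversely.
UpSet regions are exclusive membership patterns, disjoint and exhaustive
over the union.

## Cell-cell communication

Cluster expression is the truncated mean (⌊n·trim⌋ dropped per tail,
trim = 0.13) of log-normalized expression over clusters with ≥ 20 cells;
smaller clusters are removed and logged. The interaction function is a
first-order saturating form raw = LR/(K + LR) with K = 0.5, ligand level L
from the sender, receptor level R as the geometric mean of subunit levels
in the receiver (zero if any subunit is absent — receptor-complex logic);
population-size scaling multiplies by (nᵢ/N)(nⱼ/N). The referenced
communication tool's full model (Hill co-factor kinetics) is not specified
in the source text; this simplified form preserves its monotone,
saturating, mass-action character and is a declared stand-in, not a claim
of equivalence. Significance: cluster labels are permuted over cells
(cluster sizes preserved), p = (1 + #{perm ≥ obs})/(n_perm + 1) — the
add-one estimator avoids p = 0 and gives a floor of 1/(n_perm + 1) — and
entries above α = 0.05 are zeroed. Networks aggregate significant entries
to count and strength matrices; centralities are row sums (sending), column
sums (receiving) and their total (influence), each rescaled to [0, 1] by
its maximum with all-zero vectors left at zero.

## Enrichment and composition

ORA: p = P(X ≥ k) for a hypergeometric draw of the n-gene query from the
M-gene universe containing K set members; fold enrichment (k/n)/(K/M); BH
within each set-category label separately, mirroring per-ontology testing.
Gene-set collections are user-supplied GMT files — no ontology download or
identifier conversion, avoiding external-database version dependence.
Composition reports per-sample and per-condition pooled cell-type
fractions, which sum to 1 per grouping to 1e-12.

## Numerical and design notes

- Trigamma inversion uses the standard Newton scheme with asymptotic
  starting values; variance-prior estimation excludes non-positive s².
- TSV floats are serialized at 10 significant digits; reruns with the same
  configuration and seed are byte-identical (covered by a test).
- Matrix Market triplets are validated as 1-based before parsing; 0-based
  files are rejected with an explicit message.
- Problem sizes in the test suite and acceptance script (e.g. 5–20 repeated
  cohorts, 500-gene null matrices, 400-cell communication cohorts) were
  chosen as the smallest sizes at which the statistical claims under test
  are comfortably identifiable.

## Known limitations

- The paired bulk engine is a moderated linear model, not a
  negative-binomial Wald test; with 3 patient pairs its raw p-values are
  approximate and the planted-recovery results quantify its behaviour only
  under the NB simulation.
- The communication model omits agonist/antagonist co-factors and
  pathway-level re-testing, and its half-saturation constant is a fixed
  default rather than a fitted quantity.
- Wilcoxon p-values for large groups rely on the normal approximation;
  discreteness of counts makes them slightly conservative at very low
  expression.
- The ortholog map is an input; no ortholog inference is performed.
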