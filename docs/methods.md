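# Methods

This note documents the models, conventions, parameter defaults, and design
choices behind `parabio_rescue`, in the spirit of a statistical methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic data model

The generator (`simulate.GeneratorParams`, `generate_dataset`) draws a
four-group (Yiso / Aiso / Yhet / Ahet) single-cell count matrix with known
structure:

- **Baseline expression.** Each gene receives a baseline drawn log-uniformly
  over `baseline_log10_cp10k = (-1.3, 2.3)` and rescaled so baselines sum to
  10,000 — i.e. baselines are true counts-per-10k (CP10K). This spans the
  four orders of magnitude typical of droplet scRNA-seq.
- **Counts.** For cell *c* and gene *g*, the mean is
  `libsize_c · frac_g · 2^offset(type, group, g)` and counts are
  gamma-Poisson: `lambda ~ Gamma(theta, mu/theta)`, `count ~ Poisson(lambda)`
  with a single global inverse-dispersion `theta = dispersion = 10`
  (variance `mu + mu²/10`, clearly super-Poissonian at moderate expression).
  Per-cell depth is log-normal around `mean_depth = 5000` with
  `libsize_sigma = 0.35`, mean-corrected so E[depth] equals `mean_depth`.
- **Effects are additive on log2 mean expression before depth scaling**, so
  a planted offset *is* the expected log2 fold change of the gene's relative
  expression.
- **Cell types and markers.** `n_cell_types` types (default 3), each with
  `markers_per_type = 20` marker genes up-shifted by
  `marker_log2_effect = 2` in their own type only (zero cross-type leakage
  of the effect; baseline expression is shared). Marker-based assignment is
  therefore solvable but not trivial.
- **Aging programs.** Each type carries `aging_genes_per_type = 100` program
  genes with signed offsets of magnitude `aging_log2_effect = 1` in aged
  animals. Signs are mixed 1:2 up:down, so the extra transcriptome mass of
  doubled genes is balanced by the mass removed from halved genes and the
  per-cell total stays nearly constant across groups. Without this, depth
  renormalization during CP10K scaling would deflate every fold-change
  estimate by the group depth ratio (a real compositional artefact of
  relative-abundance data; the generator removes it by construction so
  planted effects are realized unbiasedly).
- **Program eligibility.** Program and marker genes are drawn from the
  `program_quantile_band = (0.70, 0.98)` quantile band of baseline
  expression (non-mito genes). For the default panel this is roughly CP10K
  5–50: well enough expressed that a 2-fold change survives the pseudocount
  in the fold-change estimate, while excluding the extreme top of the
  distribution.
- **Rescue and acceleration.** A seed-chosen fraction `rescue_fraction`
  (default 0.5, scalar or per-type) of each type's program is reverted in
  Ahet by `rescue_magnitude` × the aging effect (default 1.0 = full
  reversion); the complementary subset is untouched and grounds specificity
  tests. `accel_fraction` / `accel_magnitude` recapitulate the aging effect
  in Yhet analogously.
- **Hub gene.** One gene (`hub_gene`, default `Hub1`) is planted in the
  aging program of `hub_n_types` types (default: all), always down-regulated
  with aging and always in the rescued subset — it is the planted systemic
  rejuvenation target, and it is also placed in the generated
  "aging database" gene set together with a sample of other program genes
  and random background padding. `n_shared_aging_genes = 10` additional
  genes recur in up to `shared_gene_n_types = 3` types' programs so the
  frequency ranking has non-trivial competition.
- **QC structure.** 2 % of genes carry the `mt-` prefix and are scaled to
  5 % of total expression. Optional fractions of cells are planted to fail
  QC: `lowq_cell_fraction` cells restricted to 150 expressed genes,
  `himito_cell_fraction` cells with mito counts boosted ~10×.

What the generator does **not** emulate: doublets, ambient RNA, batch
effects, gene–gene correlation beyond the shared programs, per-gene
dispersion, trajectory structure. Passing tests therefore demonstrate
correctness of the statistical machinery on overdispersed sparse counts with
realistic depth variation — not robustness to every artefact of real
droplet data.

The null generator (`null_dataset`) uses the same sampling scheme with every
effect forced to zero and a ground truth marking all genes background.

## Preprocessing

- QC keeps cells with `n_genes_detected > 200`, `< 4000`, and
  `pct_mito < 20 %`; all three inequalities strict. `pct_mito` is computed
  on raw counts as 100 × (counts on `mt-`-prefixed genes) / (total counts).
  QC is idempotent and always precedes normalization.
- Normalization is natural-log CP10K:
  `log(1 + 1e4 · count / cell_total)`, the de-facto default of the standard
  single-cell toolchains; the scale is configurable. Cells with zero totals
  are rejected by name.
- Cell types are assigned by the argmax of per-type marker module scores,
  with a cell left `unassigned` when the winning margin is below
  `min_margin = 0.05` (on the module-score scale; in synthetic sweeps this
  only excludes genuinely ambiguous cells). Exact ties resolve to the
  lexicographically first type; a single candidate type always wins
  (runner-up −∞). Assignment by scoring rather than graph clustering keeps
  the step deterministic and directly testable against planted truth.

## Differential expression

- Per (cell type × contrast) stratum, genes with a positive count in at
  least `min_cells = 3` cells of either group are tested (the detection
  floor avoids degenerate all-zero tests; it is exposed and recorded).
- The two-sided Wilcoxon rank-sum test uses midranks. When
  C(m+n, m) ≤ 2·10⁵ the p-value is exact: the permutation probability
  P(|W − E[W]| ≥ |w − E[W]|) by enumeration over all m-subsets (the midrank
  multiset is symmetric about its mean, so this equals the doubled
  one-sided tail). Otherwise the normal approximation with tie correction
  and a 0.5 continuity correction is used; the vectorized bulk path is
  asserted identical to the scalar path, and both match the reference
  asymptotic implementation in scipy on random data.
- log2FC = log2[(mean(expm1 x) + 1) / (mean(expm1 y) + 1)] over the
  normalized layer — the ratio of group-mean CP10K with pseudocount 1.0
  (configurable), a widespread single-cell convention. The pseudocount
  slightly shrinks estimates of low-expressed genes toward zero; program
  genes in the generator sit where this bias is small.
- BH adjustment is step-up with a right-to-left cumulative minimum, applied
  within the stratum's test family (matching per-cell-type DEG reporting);
  a global correction across strata is available by pooling records before
  thresholding.
- DEG criteria: |log2FC| > 0.25 **and** adjusted p < 0.05, both strict, so
  a gene sitting exactly on either boundary is excluded.

## Rescue classification

- **Strict mode (default):** PR requires opposite directions in the Aged
  and Ahet tables; PG requires concordant directions in Aged and Yhet. A plain
  intersection definition is ambiguous, but the up/down
  stratification of the rescue definition and its interpretation (reversal
  toward youth; recapitulation of aging) imply directionality.
- **Loose mode** keeps the plain intersections and is reported alongside;
  strict-PR and the concordant remainder partition loose-PR.
- Percentages are per cell type, never pooled; a type with zero Aged-DEGs
  has undefined percentages (NaN, flagged, listed last) rather than a
  division by zero.

## Gene-set scoring

- **Module score:** genes are binned into `n_bins = 25` equal-frequency
  bins of average normalized expression (equal-width available behind a
  flag; quantile binning is robust to the skewed mean distribution); each
  set gene draws `n_ctrl = 100` control genes from its bin, with
  replacement when the bin is smaller; the score is mean set expression
  minus the mean over the pooled control draw. Sampling is seeded and the
  defaults are the established ones for this scoring scheme. The score is
  exactly zero on a constant matrix and invariant to adding a constant to
  the normalized layer.
- **Rank-AUC score:** per cell, genes are ranked by descending expression
  with ties broken lexicographically by symbol; the score is the area
  under the set-gene recovery curve within the top
  `top_fraction = 0.05` of ranks, normalized by its maximum, hence in
  [0, 1] and invariant to monotone transforms of the cell's expression.
  This serves regulon-style activity scoring of user-supplied target-gene
  lists (network inference itself is out of scope).
- Group comparisons use the same rank-sum test on per-cell scores with BH
  across the pairs tested in the call.

## Prioritization

- Overlap with aging collections matches gene symbols verbatim and
  case-sensitively — no alias or ortholog mapping, so reported overlaps are
  conservative and never silently inflated.
- Frequency counts **distinct cell types** (a gene hit in two contrasts of
  one type counts once). The default contrast scope is {Aged, Ahet} — the
  tables from which PR classification is built; the scope is configurable
  and recorded in the run report.
- Ties are broken by summed |log2FC| over the gene's in-scope records, then
  by symbol, so candidate tables are fully deterministic.
- The hypergeometric over-representation p-value is computed by exact
  integer summation of the upper tail. The default universe is the genes
  actually tested in the analyzed stratum (expressed-gene background), which
  avoids the inflation that a whole-genome universe produces for sets of
  well-expressed genes.

## Pipeline and reproducibility

- One master seed fans out to per-stage seeds via `crc32("stage:seed")`
  (kept below 2³¹), so any stage can be re-run in isolation and reproduce
  its saved output.
- All result tables are TSV with a fixed column order, ≥ 10 significant
  digits for floats, and deterministic row ordering (DEGs: cell type,
  contrast, ascending adjusted p, symbol); the Matrix Market bundle stores
  genes × cells, the prevalent exporter convention, and the reader
  transposes. Identical config and seed give byte-identical outputs; the
  run report embeds the analysis config (output location excluded) and its
  hash.
- The report marks which defaults mirror the published protocol (QC bounds,
  fold-change and alpha thresholds) versus this package's own choices
  (pseudocount, detection floor, scoring defaults, margins).

## Problem sizes used by the tests and the acceptance script

Calibration and recovery run at 3 cell types × 200 cells per group per type
(2,400 cells, 1,500 genes); rescue analyses at 2 types; prioritization at
8 types × 200 cells per group (6,400 cells, 2,500 genes, 60 program genes
per type) with the hub in 6 types; module-score checks at 1 type. Rates are
averaged over 10–20 independent seeds. These sizes give the rank-sum test
ample power at the planted 1.0-log2 effects while keeping a full run of the
suite in the minutes range.

## Known limitations

- The exact rank-sum path enumerates subsets; for samples with
  C(m+n, m) > 2·10⁵ p-values are asymptotic (with tie and continuity
  corrections), as in the standard toolchains.
- Verbatim symbol matching understates overlap with collections that use
  different nomenclature (e.g. human orthologs of mouse genes).
- The compositional balance of planted programs is a generator design
  choice; on real data, strongly asymmetric transcriptional programs will
  bias CP10K-based fold changes, as they do in any relative-abundance
  analysis.
- Batch correction, embedding, clustering and network inference are out of
  scope; regulon gene lists are accepted as input, not inferred.
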