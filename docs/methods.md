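# Methods

This note documents the models and procedures implemented in `fringescope`,
their assumptions, defaults, and numerical choices. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The fringe discriminant

Hot-spring outflows cool, degas CO₂, and oxygenate downstream; the point
where phototrophs first appear (the photosynthetic fringe) tracks that
geochemical relaxation. The fringe score is a fixed linear combination of
20 geochemical variables — pH, conductivity (μS/cm), temperature (°C), DIC
and DOC (mg C/L), DO and Fe(II) (ppm), total sulfide (ppb), phosphate and
total ammonia (ppm), and ten trace metals (ppb) — with zero intercept and a
decision threshold of 0.13: scores at or above the threshold are called
photosynthetic. The published weights are shipped verbatim as a text
resource (`resources/published_lda.tsv`) and are never re-derived; the
historical training data behind them are not distributed.

Choices worth making explicit:

- **Intercept.** The published equation carries no intercept; all offset
  lives in the 0.13 threshold.
- **Tie rule.** A score exactly at the threshold classifies as
  photosynthetic (`≥`). The boundary case needs a closed decision for
  determinism.
- **Units.** Scoring requires each variable in the unit the weight was fit
  in. `fringescope.units` converts molal ↔ mass units under a density-1
  convention (1 μmolal of a species of molar mass M g/mol = M ppb);
  sulfide converts as HS⁻ (33.073 g/mol) and ammonia as NH₄⁺ (18.039
  g/mol) by default. The registry is open, so total sulfide can instead be
  booked as H₂S or elemental S if a user prefers that convention.
- **Missing variables.** Field campaigns rarely measure all 20 variables at
  every site; `lda_score` accepts declared fallback values (the analogue of
  substituting historical data) and otherwise refuses to score, naming the
  missing variable.

**Training.** `train_lda` is the closed-form Fisher two-class discriminant
w ∝ S⁻¹(μ₁ − μ₀) with pooled within-class covariance S, scaled so scores
have unit pooled within-class variance and oriented so the photosynthetic
class scores higher. A ridge of 1e-8·tr(S)/p is added only when S is
singular. Trained models are a separate capability from the published
model and never silently substitute for it. `select_threshold` scans
midpoints between adjacent sorted unique scores (plus one position below
and above) and minimizes FP + FN, breaking ties toward the smaller
threshold. `select_equidistant_sites` minimizes
‖ |s_at − s_above| − |s_below − s_at| ‖ over all candidate pairs,
breaking ties toward the pair closest in rank to the fringe.

## Synthetic outflow studies

The generator exists so that every downstream stage can be validated
against known truth. It emulates:

- **Geochemical relaxation.** Each variable follows
  `end + (src − end)·exp(−κ d)` down the transect with additive Gaussian
  noise (negative draws clipped to 0; pH clipped into [0, 14]).
  Exponential relaxation is the simplest law with a source boundary
  condition; the real mechanism (conductive cooling, degassing,
  atmospheric equilibration) is not modelled. Temperature, DIC, sulfide,
  and conductivity decay; pH, DO, DOC, ammonia, and nitrate rise.
- **Across-spring covariation.** The default 12-spring study spans source
  pH 2–9 (4 acidic, 3 circumneutral, 5 basic springs, matching the field
  design) with source chemistry coupled to pH the way Yellowstone springs
  are: basic springs are DIC-rich; acidic springs carry more DOC, ammonia,
  and conductivity. This coupling produces the observed pooled sign
  structure (e.g. r(T, DO) < 0, r(pH, DIC) > 0).
- **Niches.** Taxon intensity is a separable Gaussian in pH and
  temperature: λ = peak·exp(−Δ(pH)²/2σ²_pH)·exp(−Δ(T)²/2σ²_T). The default
  community has 60 taxa (24 phototrophs, 36 chemotrophs) with optima on
  deterministic grids across pH 1.5–9.5 and 30–95 °C, tolerances of 1.1 pH
  units and 12 °C — broad enough that communities overlap between adjacent
  sites, narrow enough that composition turns over along a transect.
- **Photosynthesis limits.** Phototroph intensity is forced to exactly 0
  wherever T exceeds 73 °C (pH ≥ 4) or 56 °C (pH < 4). An optional sulfide
  threshold can additionally suppress phototrophs but is **off by
  default**: community-level analyses do not support sulfide as a primary
  control, and the generator's defaults are the study conditions, not a
  dial.
- **Counts.** Sample library sizes are lognormal (median 2·10⁴, log-sd
  0.4, the order of a typical MiSeq amplicon library); counts are one
  multinomial draw per sample conditioned on the library size, so depth
  normalization is a real, testable step rather than a no-op.
- **Truth.** The fringe of a transect is the first downstream site whose
  expected phototroph relative abundance exceeds 1% — the same salience
  cut used throughout the class-level descriptions. Ground truth records
  expected abundances, guild labels, per-spring fringe indices, and the
  per-sample photosynthetic flag.

What the generator does **not** emulate: compositional correlation induced
by sequencing, chimeras/contamination, phylogenetic structure among taxa,
spatial autocorrelation beyond the smooth gradient, multi-channel springs,
and temporal variability. Passing recovery tests therefore demonstrates
the statistical machinery is correct, not that real outflows are this
easy.

## Community metrics

- **Normalization:** x′ᵢⱼ = (xᵢⱼ/Nⱼ)·mean(N). Preserves within-sample
  proportions exactly; columns sum to the mean library size.
- **Shannon diversity** in nats over positive proportions (the ecology
  default); the index is invariant to count rescaling, so raw and
  normalized tables agree. Group comparisons across above/at/below fringe
  labels use the Kruskal–Wallis rank test (midranks for ties).
- **Bray–Curtis:** d = Σ|x−y|/Σ(x+y); undefined (an error, never a silent
  0) between two all-zero samples.
- **Pearson matrix** on pairwise-complete observations (≥ 3 pairs), with
  per-pair n reported and zero-variance variables yielding NaN.
- **Class aggregation:** ASVs display at class rank unless an override
  names a lineage taxon at another rank (e.g. a phylum displayed whole, or
  unidentified reads binned at domain). Display taxa whose percent
  abundances summed over all samples are ≤ 20 (strict >) collapse into
  "Other". Columns always total 100%.

## Ordination

**NMDS.** Kruskal's non-metric scheme on a Bray–Curtis matrix: within each
run, alternate (i) pool-adjacent-violators monotone regression of the
configuration distances on the rank order of the observed dissimilarities
(tied dissimilarities are pooled to a common disparity) with (ii) a
Guttman-transform update of the configuration. Stress is
stress-1 = √(Σ(d̃ − d̂)²/Σd̃²) over disparities d̃ and configuration
distances d̂; an update that would raise stress is step-halved toward the
previous configuration, so stress is non-increasing within a run by
construction. Defaults: k = 2, 20 restarts (classical-scaling warm start +
19 seeded random starts), 300 iterations, tolerance 1e-7. The best
configuration is centered and rotated to principal axes; scale is
arbitrary, as always in NMDS.

**envfit.** Each variable is regressed (least squares) on the ordination
axes; r² = 1 − SS_res/SS_tot, the arrow is the unit-normalized coefficient
vector, and p = (1 + #{r²_perm ≥ r²_obs})/(n_perm + 1) under random
permutation of the variable across samples (999 permutations by default,
one-sided with the +1 correction). Constant variables are flagged
undefined.

**RDA percent contribution.** For a single centered constraint x:
100·tr(ŶᵀŶ)/tr(YᵀY) with Ŷ the projection of the column-centered
community matrix onto x — the *marginal* attribution, so single-variable
percentages do not sum to the combined (span) percentage unless the
constraints are orthogonal. Abundances enter untransformed (no Hellinger),
matching the plain normalized-table workflow; a transformation hook would
be a straightforward extension. Collinear constraint sets are rejected
with the dependent columns named.

**CCA group test.** Abundances are chi-square standardized,
Q = (P − rcᵀ)/√(rcᵀ); constrained axes come from √r-weighted regression
of Q on dummy-coded fringe groups followed by SVD, giving (groups − 1)
axes with non-increasing eigenvalues. Per-axis significance permutes the
raw group labels (a simple null; residualized permutation schemes exist
but the simple null is exact under exchangeability of labels) and compares
each observed eigenvalue to its permuted distribution with the same
+1-corrected estimator. Pseudo-F uses residual inertia over n − g degrees
of freedom.

All permutation p-values lie on the lattice {i/(n_perm+1)} and are exactly
reproducible under a fixed seed.

## Co-occurrence network

ASVs with total reads > 20 and occurrence in > 3 samples (both strict, on
raw counts) become nodes; edges join pairs with Spearman ρ > 0.7 computed
on normalized abundances across all samples. The rule is signed —
negative correlations never form edges — with an absolute-value mode
behind a flag. "Cliques" are Louvain communities of the unweighted edge
graph (edges are thresholded, not weighted, so unweighted modularity is
the consistent objective).

Louvain is greedy and order-dependent. The implementation sweeps nodes in
ascending id order first and then runs 9 further seeded-shuffle restarts,
keeping the best-modularity partition; the whole procedure is
deterministic given (seed, n_restarts). The stored modularity is always
recomputed independently from the final membership. On some graphs *no*
sweep order reaches the globally optimal partition — a known property of
the heuristic, not an implementation defect — so for tiny graphs
(≤ 10 nodes) `check_optimality=True` certifies the result against
exhaustive partition enumeration and records the verdict in
`is_global_optimum`. Clique ids are renumbered 1..K in order of first
appearance; isolated nodes are singleton cliques.

Node–geochemistry association is Spearman ρ between each ASV's abundance
profile and each variable; cliques are summarized by the member median.
Constant profiles yield NaN, flagged rather than zeroed.

## Pipeline and reproducibility

`run_pipeline` executes the stages in a fixed order and writes one TSV per
stage plus `manifest.json` (config snapshot, per-stage seeds, output
paths, 4-significant-digit summary statistics, package version,
timestamp). Every random stage draws its seed from the root seed expanded
through a `SeedSequence` keyed on the stage name, so stages rerun in
isolation reproduce their outputs; reruns with the same config and seed
are bit-identical apart from the timestamp.

Problem sizes used by the test suite and the acceptance script — the
default 48-sample/60-taxon study, 10–20 replicate studies for recovery
medians, 99–999 permutations, 100 small graphs for the Louvain oracle —
were chosen to exercise every code path at the scale of a real transect
campaign while keeping a full run in the order of seconds to a few
minutes.

## Known limitations

- The published discriminant cannot be re-derived here (training data
  unpublished), so its weights are trusted as printed; two garbled
  typesettings of the equation exist in circulation and the shipped
  resource follows the internally consistent reading.
- NMDS stress is reported for the returned local optimum; no global
  optimality is claimed (restarts mitigate, never guarantee).
- RDA on raw normalized abundances implies a linear response model;
  long-gradient data may warrant a transformation before constrained
  ordination.
- The CCA per-axis test permutes labels identically for every axis; axes
  beyond the first inherit conservatism from the sequential eigenvalue
  structure.
- Spearman co-occurrence ignores compositionality; SparCC-style
  corrections are out of scope.
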