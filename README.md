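# fringescope

Statistics for the **photosynthetic fringe** of hot-spring outflows — the
first downstream point in an outflow channel where phototrophic pigments
appear, marking the transition from purely chemotrophic communities to
communities that also host phototrophs.

The package is aimed at geobiologists and microbial ecologists working with
paired geochemistry + 16S rRNA amplicon (ASV) tables from outflow
transects. It provides, as one tested pipeline:

- **A geochemical fringe score.** A fixed linear discriminant over 20
  geochemical variables,

  *LDA* = 1.028·10⁻¹ pH + 6.769·10⁻⁵ cond(μS/cm) − 6.12·10⁻² T(°C)
  + 2.037·10⁻⁴ DIC + 7.199·10⁻³ DOC + 1.746·10⁻¹ DO(ppm)
  − 2.610·10⁻² Fe(II) − 9.36·10⁻⁵ ΣHS⁻(ppb) − … − 2.35·10⁻² ΣPb(ppb),

  with decision rule *LDA* ≥ 0.13 → photosynthetic. The published weights
  ship as a versioned text resource; a Fisher two-class trainer can fit new
  models of the same shape, and helpers pick minimum-error thresholds and
  score-equidistant above/below sampling sites.
- **Community metrics.** Depth normalization (relative abundance × mean
  library size), Shannon diversity (nats), Kruskal–Wallis diversity tests
  across fringe groups, Bray–Curtis dissimilarity, pairwise-complete
  Pearson matrices for geochemistry, and class-level percent-abundance
  tables with "Other" binning.
- **Ordination statistics.** Kruskal NMDS (pool-adjacent-violators
  monotone regression + Guttman updates, stress-1, restarts), `envfit`-style
  vector fitting with permutation p-values, RDA percent-variance
  attribution (marginal and combined), and CCA fringe-group tests with
  per-axis permutation ANOVA.
- **Co-occurrence networks.** ASV filtering (> 20 reads, > 3 sites),
  Spearman edges (ρ > 0.7), Louvain cliques with certified-optimality
  diagnostics on tiny graphs, and node/clique correlations with
  geochemistry.
- **A synthetic outflow generator** producing multi-spring transect studies
  with known fringe positions, Gaussian pH × temperature niches, and hard
  phototroph suppression above the pH-dependent photosynthesis limit
  (~73 °C at circumneutral/basic pH, ~56 °C below pH 4), so every stage of
  the pipeline can be exercised and validated without any external data.

## Worked example

```python
from fringescope import simulate_study, normalize_counts, bray_curtis
from fringescope.ordination import nmds, envfit
from fringescope.pipeline import fringe_recovery_cv

ds, truth = simulate_study(seed=7)          # 12 springs × 4 sites
acc = fringe_recovery_cv(ds, truth, seed=7)
print(f"cross-validated fringe accuracy: {acc:.3f}")

dist = bray_curtis(normalize_counts(ds.counts))
ordn = nmds(dist, seed=7)
print(f"NMDS stress: {ordn.stress:.4f}")
for f in envfit(ordn, ds.geochem, ["pH", "temperature", "sulfide"], seed=7):
    print(f"envfit {f.variable}: r2={f.r_squared:.3f}, p={f.p_value:.3f}")
```

prints

```
cross-validated fringe accuracy: 0.917
NMDS stress: 0.0247
envfit pH: r2=0.998, p=0.001
envfit temperature: r2=0.988, p=0.001
envfit sulfide: r2=0.753, p=0.001
```

meaning: a discriminant trained on the synthetic geochemistry recalls the
generator's true photosynthetic/non-photosynthetic split for ~92% of
held-out samples; the two-dimensional NMDS embeds the 48-sample
Bray–Curtis matrix with low stress; and the fitted geochemical vectors
confirm that pH and temperature (the variables that actually drive the
simulated niches) align tightly with the ordination.

The same analysis runs end to end from the shell:

```sh
fringescope simulate --seed 42 --out study/        # writes the four TSVs + truth
fringescope score --geochem study/geochem.tsv      # published-model fringe calls
fringescope run --config cfg.yaml --seed 42 --out out/   # full pipeline + manifest
```

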