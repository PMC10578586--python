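# Methods

This note documents the model, the numerical choices, the statistical
procedures, and the synthetic-data generators, together with the assumptions
and known limitations of each.

## 1. Colony surface model (`surface_model`)

### Equations

State variables on a radially symmetric domain `r ∈ [0, R_max]`, per genotype
`i`: vegetative biomass density `V_i(r, t)`, spore density `S_i(r, t)`, and a
shared nutrient field `N(r, t)`:

```
∂V_i/∂t = D_b,i ∇²V_i + μ_i g_i(N) V_i − σ_i h_i(N) V_i
∂S_i/∂t = σ_i h_i(N) V_i
∂N/∂t   = D_N ∇²N − Σ_i (μ_i / Y_i) g_i(N) V_i
g(N) = N / (K_g + N)              (Monod growth)
h(N) = K_s^m / (K_s^m + N^m)      (starvation-triggered sporulation, Hill)
```

Assumptions: radial symmetry; colony expansion as effective biomass diffusion
(sliding motility, no explicit mechanics); spores are immobile and inert; one
limiting nutrient; no mutation during growth (genotypes are fixed inputs);
zero-flux boundaries at `r = 0` (symmetry) and `r = R_max` (closed dish).

### Default parameters

| symbol | default | units | rationale |
|---|---|---|---|
| `D_b` | 0.01 | mm²/h | yields a front speed ≈ 0.1 mm/h, i.e. a ~17 mm colony in one week, matching plate-scale growth |
| `μ_max` | 0.3 | 1/h | doubling time ≈ 2.3 h on fresh medium |
| `σ_max` | 0.03 | 1/h | starvation converts most standing biomass to spores within ~2 days |
| `K_g` | 0.2 | nutrient units (N0 = 1) | growth at half speed when 20% nutrient remains |
| `K_s` | 0.3, `m` = 4 | — | sporulation switches on sharply below ~30% nutrient |
| `Y` | 1.0 | biomass/nutrient | units absorbed into the nutrient scale |
| `D_N` | 0.01 | mm²/h | nutrient diffuses on the same scale as biomass spreads |
| domain | `R_max` 25 mm, 251 nodes | dr = 0.1 mm | dish radius with ≥ 10 nodes across the transfer annulus |
| protocol | 168 h cycles, 1.5 mm edge annulus, 0.5 inoculum mass over 2 mm | | weekly passage of the outermost rim |

These defaults were chosen once, from the qualitative behaviors they must
produce (growing front, center starvation, center-biased sporulation, all
selection directions), and then frozen; they are not fitted to any dataset.

### Numerics

- **Spatial discretization.** Conservative finite-volume radial Laplacian:
  node `i` owns the annulus `[r−dr/2, r+dr/2]` with weight
  `w_i = π((r+dr/2)² − (r−dr/2)²)`; fluxes are evaluated at annulus faces, so
  pure diffusion conserves `Σ w_i f_i` to round-off. The `r = 0` node reduces
  to the symmetric limit `4D (f_1 − f_0)/dr²`.
- **Time stepping.** Explicit Euler with `dt ≤ 0.4 dr²/max(D)` and an
  additional reaction cap `0.1/max(μ, σ)` (`stable_dt`).
- **Positivity of N.** Explicit Euler on the consumption term can drive `N`
  slightly negative ahead of a steep biomass front. Consumption is therefore
  applied as an exact exponential factor per step,
  `N ← N·exp(−q·dt) + dt·D_N ∇²N` with `q = Σ (μ_i/Y_i) V_i/(K_g,i + N)`,
  which is positivity-preserving and agrees with Euler to `O(dt²)`. Fields
  are checked every step; values below `−1e−12` raise instead of being
  silently clipped.
- **Verification.** Pure-diffusion mass conservation (1e−6 relative over 1000
  steps), agreement of the reaction terms with an independent `solve_ivp`
  scalar integration (1e−4 relative), and Fisher–KPP front speed
  `c = 2√(D_b · μ g(N0))` within 20% on a fine grid with frozen nutrient.

### Passaging and sweeps

`edge_transfer` harvests all biomass (vegetative + spores, per genotype) from
the annulus `[R − edge_width, R]` of the grown colony, where `R` is the radius
at which total biomass density crosses `biomass_threshold`, and re-inoculates
a fresh plate at fixed total mass with genotype proportions preserved.
`selection_sweep` competes a one-parameter mutant against the wild type from a
50:50 start and reports the mutant's final edge share. Neutral competition is
a fixed point to 1e−6 over five passages, which bounds the numerical bias of
the whole growth–transfer loop.

## 2. Regulator activity and modules (`regulon`)

- **Normalization.** Median-of-ratios size factors (geometric-mean reference,
  factors rescaled to geometric mean 1), then `log2(count/factor + 1)`.
- **Activity.** For regulator `R` with target set `T`: z-score each target
  gene across the sample set, average over `T`, multiply by +1 (activator) or
  −1 (repressor). Zero-variance targets are dropped; regulons with no usable
  target are reported as undefined rather than imputed. Activity is a
  statement about the targets, not about the regulator's own transcript;
  `own_expression_fits` quantifies how well the regulator's own expression
  tracks its inferred activity.
- **Coactivation and modules.** Pearson correlation of activity vectors;
  modules by average-linkage hierarchical clustering on distance `1 − r`, with
  `k` chosen to maximize the silhouette over `k ∈ 2..6` (ties toward smaller
  `k`). If the best silhouette is below 0.1 the partition is flagged
  degenerate — the data do not support modular structure and the caller must
  not interpret the labels.

## 3. Expression statistics (`expression`)

- **DE screen.** Two-sided Mann–Whitney U per gene between two disjoint sample
  groups, Benjamini–Hochberg adjustment, significance = `p_adj < α` and
  `|lfc| ≥ lfc_min`. `lfc` is the difference of group means of the
  log2-normalized values (group B minus group A). Rank tests are used because
  per-condition replication is small and count distributions are skewed; the
  cost is discreteness of attainable p-values at small n.
- **Overlap and enrichment.** Two-sided Fisher exact tests on 2×2 tables over
  an explicit gene universe; enrichment is evaluated for the `k` largest
  regulons (default 40) to avoid powerless tests on tiny sets.
- **PCA.** Samples × genes, mean-centered per gene, full SVD; scores,
  loadings, and explained-variance fractions are returned together.
- **Oracles.** The tests verify BH against a brute-force step-up
  implementation, Fisher p-values against full hypergeometric enumeration for
  table margins ≤ 30, and the DE screen's type-I rate under a simulated null.

## 4. Self-organizing map and operon coherence (`som`)

Batch Kohonen algorithm on a hexagonal grid: all genes are assigned to their
best-matching unit, then every codebook is recomputed as the
neighborhood-weighted mean, with a Gaussian neighborhood whose radius shrinks
linearly from half the grid diameter to 0.5 over the epochs. Batch training
plus seeded initialization (codebooks drawn from data rows) makes training
exactly reproducible — required because downstream permutation tests condition
on the trained map.

Operon coherence statistics, given gene → operon and gene → (start, strand)
maps: per-unit operon diversity and per-operon meta-gene diversity as relative
Shannon indices `H/ln(n)` (0 = pure, 1 = maximally mixed); start-coordinate
distances between same-unit genes computed per strand and compared with
label permutations; and a same-operon co-assignment permutation test with
`p = (1 + #{null ≥ observed}) / (n_perm + 1)`.

## 5. Colony outline (`outline`)

1. **Dish detection.** Otsu threshold, morphological closing, largest
   component, algebraic (Kåsa) circle fit. Components touching the image
   border are exempt from the circularity gate and flagged `truncated`;
   border pixels are excluded from the fit.
2. **Segmentation.** Otsu threshold restricted to the dish interior, largest
   component, sub-pixel contour by marching squares, resampled to 360
   equally spaced (arc-length) points.
3. **Refinement.** Sample the image along the outward normal at each point
   (bilinear interpolation, ±L px), fit the logistic
   `I(x) = a + b/(1 + exp(−(x − x0)/s))`, and move the point to the fitted
   inflection `x0` when the fit converges and `|x0| ≤ max_shift`. Shifts are
   smoothed with a circular moving median; if the refined polygon
   self-intersects, the largest shifts are reverted until it is simple.
   Near-constant profiles are rejected before fitting (flat images must be a
   no-op). This recovers the boundary to sub-pixel accuracy under smooth
   illumination gradients that bias a global threshold.
4. **Radius.** Equivalent-area radius `√(area/π)` from the shoelace polygon
   area; `process_series` applies the pipeline per image with per-image
   failure isolation and optional mm conversion.

## 6. Synthetic data (`synth`)

Purpose: ground-truthed inputs for validating the analysis pipelines. Scope
and deliberate simplifications:

- **Transcriptomes.** Genes are grouped into operons (geometric size
  distribution, capped); regulons sample whole operons with probability
  `p_within` per target. Each sample has a latent dormancy coordinate
  `d ∈ [0, 1]` increasing with colony age and center position; regulator
  activity is `±(2d − 1)` by module (vegetative vs dormancy); gene log2-means
  are `baseline + β Σ mode_sign · activity`; counts are negative-binomial
  (`var = mu + φ mu²`) at fixed sequencing depth. One latent axis only — real
  transcriptomes have additional structure; the generator is intentionally a
  best case for recovering the planted two-module split.
- **Composition tables.** Filamentous / vegetative / sporulating / spore
  fractions as fixed smooth functions of `d` on the simplex, with analytic
  anchors at `d = 0` and `d = 1`.
- **Images.** Radially symmetric plates: dark background, dish disk, colony
  disk with an erf-profile edge of adjustable width, optional linear shading
  field and Gaussian noise, written as 16-bit PNGs with a manifest. No
  texture, lighting artifacts, or non-circular colonies.

Default problem sizes (600 genes, 17 regulators, 16 samples, 512² images) are
this package's own choice: large enough for stable statistics, small enough
that the entire suite runs in minutes on one CPU.

## 7. Limitations

- The PDE model is phenomenological: expansion-as-diffusion has no cell
  mechanics, EPS, or osmotic spreading physics, and first-order sporulation
  kinetics ignore the phosphorelay's bistability and heterogeneity.
- Explicit time stepping makes fine grids quadratically expensive
  (`dt ∝ dr²`); the defaults keep runs in seconds, but high-resolution front
  studies should budget accordingly.
- Activity inference assumes regulon sign labels are correct and treats
  targets as exchangeable; dual-mode regulators and condition-dependent
  regulation are out of scope.
- Mann–Whitney p-values are discrete at small group sizes, so attained type-I
  rates sit at or below nominal α.
- The image pipeline assumes a single colony per dish and an approximately
  convex boundary; overlapping colonies or strongly lobed morphologies are
  not segmented correctly.
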