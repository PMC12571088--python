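# morphx

Landmark-based morphometrics and extinction-scenario analysis of
morphospace erosion, built around the question conservation
macroecologists keep asking: *if the threatened species go extinct, how
much morphological and ecological diversity goes with them — and is that
loss worse than random?*

The package targets datasets like requiem-shark tooth archives: 2D
landmark configurations digitized per tooth (a few fixed landmarks plus
dense semilandmark curves), a species trait table with IUCN threat
categories, a proportional diet matrix, and a phylogeny. It provides

- **shape quantification** — TPS file I/O, equidistant curve resampling,
  generalized Procrustes analysis (GPA) with bending-energy sliding
  semilandmarks, Procrustes distances and centroid sizes;
- **morphospace summaries** — species-mean PCA, convex-hull area,
  centroid shifts under species removal (in the fixed baseline
  ordination), and linear depth-surface interpolation over the score
  plane;
- **the extinction engine** — nested threat-ordered removal scenarios
  (CR, CR+EN, CR+EN+VU, CR+EN+VU+NT) tracked by hull-area loss, centroid
  displacement, survivor depth range, and disparity, against Monte Carlo
  random-extinction nulls with 95% envelopes;
- **permutation inference** — residual-randomization (RRPP) shape ANOVA
  with Goodall-style trace statistics, pairwise group contrasts, and a
  multivariate Blomberg-type K for phylogenetic signal;
- **compositional diet analyses** — centered log-ratio (CLR) transform
  with multiplicative zero replacement, ordinated dietary niche breadth
  (ODB) via prey PCoA, and homogeneity of multivariate dispersions with
  scenario-wise contraction of the surviving prey base;
- **a synthetic-data generator** that emulates all four inputs with the
  statistical structure the analyses assume, so every stage is testable
  and parameter recovery is measurable without any restricted data.

The disparity measure is the average pairwise Procrustes distance,

```
APPD = 2 / (n (n - 1)) * Σ_{i<j} d_ij
```

where `d_ij` is the Procrustes distance between aligned configurations
*i* and *j*; falling APPD means morphological homogenization. Blomberg's
multivariate K is the ratio of tip-level to phylogenetically-corrected
sums of squares standardized by its Brownian-motion expectation (K = 1
under Brownian evolution).

## Worked example

Simulate a 30-species dataset in which threat status is selective on
tooth morphology (selectivity `beta = 2`), then run the full pipeline:

```sh
mx simulate --out demo --seed 3 --beta 2.0 --teeth 2 4
mx analyze demo --seed 3 --null-reps 100 --nperm 499
```

prints

```
species: 30  specimens: 85
PC variance (%): 92.15, 6.43, 0.29, 0.13, 0.10
threatened: 73.3%
  CR           removed= 4 area_loss=  67.5% appd=0.2011 APPD vs null: below
  CR+EN        removed=12 area_loss=  82.5% appd=0.1757 APPD vs null: below
  CR+EN+VU     removed=22 area_loss=  96.1% appd=0.1607 APPD vs null: within
  CR+EN+VU+NT  removed=26 area_loss=  97.4% appd=0.2130 APPD vs null: within
```

Reading this: one dominant shape axis (PC1 ≈ 92% of variance, the
oblique-short ↔ upright-elongate crown continuum); 22 of 30 species
(73.3%) are threatened; removing only the four Critically Endangered
species already erases 67.5% of occupied morphospace area, and the
survivors' disparity (APPD) falls *below* the 95% envelope of 100 random
removals of the same intensity — extinction by threat status is
detectably non-random. At the highest intensities nearly everything is
lost, and random removal is just as destructive (`within`), the
convergence expected once most of the fauna is gone.

The same machinery is available as a library: `morphx.superimpose`,
`morphx.ordinate`, `morphx.canonical_scenarios`,
`morphx.random_extinction_null`, `morphx.perm_anova`,
`morphx.phylo_signal`, `morphx.clr_transform`,
`morphx.ordinated_breadth`, `morphx.generate_bundle`, and
`morphx.run_pipeline` for the whole chain.

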