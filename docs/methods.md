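# Methods

## Shape quantification

Each tooth is a 160-point configuration: three fixed landmarks (mesial
crown-root corner, cusp apex, distal corner) and two semilandmark curves
of 78 and 79 points on the mesial and distal crown edges. Curves are
resampled to equal arc-length spacing by linear interpolation along the
digitized polyline, which makes the sampling invariant to the
digitizer's point density.

Generalized Procrustes analysis removes translation (centroid to
origin), scale (unit centroid size) and rotation (proper least-squares
rotation to an iteratively updated consensus; reflections are never
fitted — teeth are chiral, and left-side specimens are mirrored once at
load time as a curation step). The plain GPA loop stops when the
root-mean-square change of the consensus falls below `tol = 1e-8`
(`max_iter = 100`).

Semilandmark sliding minimizes thin-plate-spline bending energy against
the current consensus. The bending-energy matrix is the upper-left block
of the inverted TPS system built from the kernel `U(r) = r² log r²` on
the consensus; it is symmetric positive semi-definite and annihilates
affine transforms. Each semilandmark is constrained to its local tangent
(central difference of its curve neighbors, with the flanking fixed
landmarks closing the ends), and the vector of signed tangent
displacements is solved jointly from the resulting linear system — since
bending energy is exactly quadratic in the coordinates, this step can
only decrease it. Two numerical safeguards matter in practice: a tiny
ridge (1e-10 of the mean diagonal) on the solve, and a trust-region cap
of one quarter of the median neighbor spacing applied as a *uniform*
scaling of the displacement vector, which preserves the descent property
while preventing semilandmark bunching when displacements would exceed
the tangent linearization's validity.

Sliding and superimposition are interleaved as outer rounds: slide all
specimens against the consensus, re-center/re-scale/re-rotate, then
re-converge the plain GPA; rounds (at most 10) stop when the total
Procrustes sum of squares changes by less than 1e-6 relative. Sliding
every iteration of the inner loop instead produces a slow limit cycle
between the consensus update and the slide targets that never meets a
1e-8 consensus tolerance; the outer-round structure converges cleanly
and reaches lower bending energy. The final solution is rotated to a
canonical orientation — consensus principal axes, major-axis sign set by
the third moment of the projections — so the output coordinates are
invariant to the orientation, position, and scale the specimens were
digitized in (verified to 1e-8 in the suite). The stored consensus is
the arithmetic mean of the aligned coordinates (its centroid size is
slightly below one when shapes differ, as for any Procrustes mean).

Species mean shapes are arithmetic means of aligned coordinates, without
re-projection to the shape manifold; at the shape variation scales
involved the curvature correction is far below the statistical noise.
Tangent-space projection before PCA is likewise not applied.

## Morphospace and extinction scenarios

PCA is an SVD of centered rows; axis signs follow a deterministic rule
(largest-magnitude loading positive) so runs are comparable. Hull area
uses the convex hull of the (PC1, PC2) scores with the shoelace formula
(degenerate point sets have area zero). Under species removal, survivor
hulls and centroids are computed in the *fixed baseline* ordination —
erosion is an overlay in one space, never a re-ordination. The depth
surface is piecewise-linear interpolation on a Delaunay triangulation of
the scores, undefined outside the data hull; linear (not spline)
interpolation is the implemented mode.

The four canonical scenarios remove CR, CR+EN, CR+EN+VU, CR+EN+VU+NT
species; with the canonical status composition (4/8/10/4/4 of 30) the
cumulative intensities are 4, 12, 22, 26. Disparity is the average
pairwise Procrustes distance (APPD) over species means by default (a
specimen-level switch exists), and Procrustes variance (mean squared
distance from the group mean, divided by group *n*) summarizes
within-group disparity. Monte Carlo nulls remove the same number of
species uniformly at random, 100 replicates per intensity, each
replicate drawn from a per-(intensity, replicate) substream of one root
seed; envelopes are the 2.5th/97.5th percentiles of the replicate
distribution (a mean ± 1.96 sd alternative would be easy to add but
percentiles make no normality assumption). Statistics per replicate:
survivor mean PC1, mean PC2, APPD. Depth ranges are reported from
surviving species' recorded maximum depths only — missing depths are
never imputed.

## Permutation inference

Shape models are tested by residual randomization (RRPP). Sums of
squares are traces of residual cross-products (Goodall-style, full data
space); the F ratio compares a full and a nested reduced model; permuted
datasets are reduced-model fitted values plus row-permuted
reduced-model residuals (for the one-way layout this reduces to label
permutation). p counts the observed statistic in its own reference set,
so p ≥ 1/(n_perm+1); the effect size Z standardizes the
log-transformed statistic within the permutation distribution (logs are
clipped to [1e-12, 1e12] so perfect-separation F = ∞ degrades
gracefully). Pairwise contrasts use the Euclidean distance between group
means with labels reshuffled within the pooled pair, and Z on the raw
distance (distances can legitimately be zero). Defaults: 999
permutations, seeds explicit. The sequential-term engine (`rrpp_terms`)
expresses covariate models — e.g. log centroid size, then species, then
their interaction, then jaw — as successive nested comparisons.

Phylogenetic signal is a multivariate Blomberg-type K: with C the
phylogenetic covariance matrix (shared root-to-MRCA path lengths) and
deviations D taken from the phylogenetic (GLS) mean,
`K = (ΣD² / ΣD·C⁻¹D) / E_BM`, where `E_BM = (tr C − n/Σ(C⁻¹)) / (n−1)`
— so K has expectation 1 under Brownian motion regardless of tree shape
(the suite verifies a mean within [0.9, 1.1] over 200 Brownian
simulations on a 30-tip tree). p permutes species across tips; Z uses
log K. The permutation standardization of log K is the implemented
interpretation of the effect size; other standardizations exist.

## Compositional diet analyses

Diet rows are renormalized on load and all-zero prey columns dropped
with a warning (they carry no information). CLR transforms each row to
log-part minus the row's log geometric mean; zeros are first replaced
multiplicatively with δ = 0.65 × the smallest nonzero proportion in the
matrix (rows renormalized), the standard pragmatic choice where the
data's zeros are rounded rather than structural truths; the factor is
configurable and a strict `error` strategy exists.

Ordinated dietary breadth (ODB) embeds prey categories by PCoA of the
Euclidean dissimilarity between their binary consumer-incidence
profiles, then sums each consumer's squared distances of its used prey
from their centroid — zero for a single-prey specialist, and
monotonically non-decreasing when prey are added to a repertoire. The
33rd/66th ODB percentiles delimit the specialist/intermediate/generalist
bands.

Dispersion homogeneity computes each species' Euclidean distance to its
own group centroid in CLR space and compares groups by a one-way F on
those distances. The permutation p reshuffles the *distances* among
groups (exchangeable under the null of equal dispersions) rather than
recomputing centroids under relabeled rows; relabel-and-recompute mixes
translated group clouds into the permuted statistic and destroys the
test's calibration, while the distance-permutation scheme holds the
type-I error at the nominal rate (verified over 200 simulations of
translated equal-dispersion clouds). The observed F agrees with the
centroid-mode dispersion statistic of independent implementations to
machine precision (cross-checked in the suite). Scenario-wise
homogenization recomputes the survivor centroid per scenario and reports
the mean and sd of survivor distances to it.

## Synthetic data generator

The generator emulates the four inputs with the structure the analyses
assume; its defaults are the study conditions of the test suite.

- **Tree**: pure-birth with the clock run one extra waiting time past
  the n-th speciation (so no zero-length tip edges), scaled to unit
  depth; 30 tips.
- **Crown template**: three parameters map deterministically to a
  160-point outline built from two quadratic Bézier edges resampled
  equidistantly. Parameter 1 is the dominant continuum — obliquity
  saturates smoothly via a sigmoid while crown height responds
  log-linearly, so the main axis couples oblique-short to
  upright-elongate crowns as real tooth morphospaces do, and strongly
  divergent species become genuine outliers instead of piling up at a
  bound. Parameters 2 and 3 (residual log height, distal-shoulder
  curvature) are clipped to the template's valid range with a warning.
  The apex is the unique global y-maximum of every outline.
- **Evolution**: Brownian motion on the tree (per-unit-depth standard
  deviations 0.2/0.12/0.05), plus a rare one-sided specialization jump:
  with probability 0.15 a species adds an exponential excursion (scale
  0.6) along the elongation axis. The jump process is what gives the
  species cloud the heavy, one-sided periphery that threat-selective
  extinction analyses are sensitive to; a pure-BM cloud is too
  symmetric and too thin-tailed for targeted removal to separate from
  the random-removal envelope, whereas specialist outlier lineages are a
  documented feature of the real systems this emulates. Jumps scale
  with √sigma2_b, so a zero-rate simulation is exactly the template.
- **Specimens**: 14–69 teeth per species (uniform; the suite scales this
  down to 2–4 for runtime), upper/lower jaws equiprobable, lower-jaw
  crowns narrowed by a fixed factor 0.85 (dignathic heterodonty), iid
  Gaussian landmark noise σ_w = 0.01 in template units (≈1% of crown
  width, a realistic digitization error).
- **Threat**: species are ranked by `β·z₁ + Gumbel(0,1)` noise, where
  z₁ is the standardized first crown parameter, and the top ranks fill
  CR(4), EN(8), VU(10), NT(4), LC(4). β = 0 makes threat independent of
  shape; β = 2 is the "strong selectivity" condition of the recovery
  experiments.
- **Traits and diets**: body length log-normal and coupled to z₁ (slope
  0.4), size classes cut at 150/300 cm; depths log-normal (median ≈100
  m); diets Dirichlet with size-class-linked concentration (0.6/1.2/2.5
  — larger species feed more evenly), proportions below 0.03 recorded
  as zeros so the matrices have the sparsity real gut-content tables
  have.

What the generator does *not* emulate: tooth-position-dependent shape
gradients along the jaw, sexual dimorphism, digitization outliers,
measurement covariance along curves, and any ecological feedback between
diet and threat. Passing tests therefore demonstrate the pipeline's
internal correctness and its statistical calibration under the stated
model, not the field validity of any biological conclusion.

## Problem sizes and determinism

The suite runs the statistical calibrations at 500 null datasets × 199
permutations (ANOVA), 200 simulations (dispersion, multivariate K), and
the recovery experiments at 50 generator seeds with 100-replicate nulls;
specimen-level fixtures use 2–4 teeth per species. These sizes give the
binomial tolerances quoted in the tests while keeping the default run
fast. Every stochastic component takes an explicit seed; replicate
streams are spawned per (intensity, replicate) from one root seed, and
one root seed reproduces a generated bundle bit-for-bit.

## Known limitations

- With sliding enabled the GPA reports `converged` against the
  outer-round criterion; the 1e-8 inner tolerance applies to the plain
  loop. Orientation canonicalization assumes the consensus is
  anisotropic (true for teeth; ill-defined for isotropic point clouds).
- The targeted-vs-random APPD detection rate at β = 2 sits near the 80%
  design point (≈0.77 over 200 seeds at the CR-only intensity); it rises
  with β and with less noisy threat assignment.
- ODB depends on the prey dissimilarity choice (Euclidean on incidence
  profiles here; Jaccard is a plausible alternative and results may
  differ by a monotone transformation).
- Procrustes variance is reported as NaN for singleton groups rather
  than borrowing information across groups.
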