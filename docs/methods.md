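# Methods

## Scope and model

The package analyses the association between a discrete lifestyle
(non- / semi- / fully fossorial) and six continuous skull-roof traits on a
rooted, time-calibrated phylogeny, and quantifies convergent evolution of
those traits across independent acquisitions of the fully fossorial state.
The stochastic backbone is Brownian motion (BM): a trait x evolves with
variance σ²·t along a branch of length t, giving the familiar tip
covariance V[i,j] = shared root-to-MRCA path length.  Three layers sit on
top of it:

* **Pagel's λ** scales the off-diagonal of V, interpolating between a star
  phylogeny (λ = 0) and pure BM (λ = 1).  λ is estimated by maximising the
  profile GLS likelihood over λ ∈ [0, 1]; an optimum outside the interval
  is clamped and flagged.  The transform is applied to the covariance
  matrix, not to branch lengths, so non-ultrametric trees (fossil tips that
  end before the present) are handled exactly.
* **Mk models** describe the lifestyle character: a k-state continuous-time
  Markov chain with rate matrix Q (equal-rates by default, all-rates-
  different optional), fitted by Felsenstein pruning.  Stochastic character
  maps are drawn by sampling joint node states (pruning + stochastic
  traceback, root prior = stationary distribution of Q by default, uniform
  optional) and then sampling each branch history conditional on its
  endpoints by uniformization.  Uniformization was preferred over rejection
  sampling because its runtime is bounded on long branches and for rare
  endpoint combinations.
* **Convergence indices.**  C1 for a pair of tips is
  1 − D_tip / D_max, where D_max is the largest distance between any two
  reconstructed states drawn one from each lineage — the tips themselves
  and their ancestors back to and including the MRCA (this inclusive
  reading keeps C1 in [0, 1]).  Ancestral states are the GLS/ML estimates
  under BM.  Focal tips are grouped into one clade per independent
  acquisition and only between-clade pairs are averaged.  C5 counts
  lineages entering the focal region of trait space: the closed [min, max]
  interval of focal tip values in one dimension (the 1-D specialisation of
  the ellipsoid region, no padding), or the minimum-area enclosing
  ellipse (Khachiyan's algorithm) of focal tip points in two dimensions,
  with a 95 % covariance ellipse available as an alternative.  Branches are
  walked as straight segments between reconstructed endpoint states; a
  branch whose parent end lies outside the region and whose segment reaches
  it counts one entry, and a root already inside counts as the first entry
  (the origin of the walk enters the space; a documented package
  convention).  Significance for both indices:
  σ² and the root state are estimated from the observed trait by ML, n_sim
  BM datasets are simulated on the same tree with one shared seed stream
  (so the C1 and C5 nulls are coupled reproducibly), the index is
  recomputed on each (the C5 region re-derived from the same focal tips),
  and p = (b + 1)/(n_sim + 1) with ties counted as exceedances.

## Morphometry

Compactness is the foreground pixel count divided by the pixel count
inside the filled outer boundary; filling treats the background as
4-connected (cavities are background regions not 4-connected to the raster
border), the standard raster convention.  Local thickness assigns each
pixel the diameter of the largest inscribed disc containing it, computed
from the Euclidean distance transform by painting discs in order of
decreasing radius; interior cavities are filled first, per the measurement
contract.  A disc centred at c with radius EDT(c) covers the pixels
strictly closer than that radius — the same rule the brute-force test
oracle uses, so the two agree exactly rather than to a tolerance.

The thickness integral runs over profile positions s ∈ [0, 0.5].  No
measurement exists at s = 0 (the first section sits at 1/3 of the
premaxilla), so the curve is extrapolated as a constant from the first
section; truncating the integral at the first section instead is exposed
as `boundary="truncate"`.  The value at s = 0.5 is linearly interpolated
between the flanking sections.

The log-compactness transform uses base 10; the base only rescales the
axis and is not mathematically determined, so it is declared as a
package constant.  Compactness is stored as a fraction in [0, 1] and
converted to percent where the transform expects it.

Overlap uses the signed distance Δ between the posterior section of the
anterior bone and the anterior section of the posterior bone, positive
when the sections are in anatomical order without overlap; this sign
convention is the one that reproduces both printed anchors (100 % for
centred equal-length bones, 0 % for exact abutment).  Values are not
clamped: gaps give negative overlap and deeply nested bones can exceed
100 %.

LOESS profile curves are tricube-weighted local linear fits evaluated on a
regular grid; the smoother is exact on linear data, which the tests use as
the degenerate check.

## Statistical inference

The phylogenetic ANOVA fits λ by ML under the full-model design, builds the
λ-transformed covariance, whitens trait and design with the inverse
Cholesky factor, and takes the classical F statistic of the whitened fit.
Inference is by residual randomization of the reduced (intercept-only)
model: permuted residuals are added back to the reduced fit and F is
recomputed, p = (b + 1)/(n_perm + 1).  With λ = 0 on a star tree this
reduces exactly to ordinary one-way ANOVA, which is tested to 1e−8.
Pairwise contrasts are absolute differences of GLS group means in the
whitened space, with p-values from the same permutation stream and Holm
step-down adjustment.

PCA defaults to the correlation matrix because the entering traits mix
units (fractions, percent, mm, ratios); covariance scaling is available.
Two-block PLS takes the SVD of the centred cross-covariance; r-PLS is the
correlation of the first singular-score pair and the permutation p shuffles
the rows of one block.  The phylogeny-vs-lifestyle wrapper uses principal
coordinates of the patristic distance matrix (axes retained to 95 % of the
positive-eigenvalue variance) against one-hot lifestyle classes; this
block construction is one reasonable choice among several and is
switchable.

## Synthetic studies and what they do (not) show

The generator emulates the statistical structure of the real study: a
pure-birth ultrametric tree (default 99 tips, birth rate 1, giving total
tree length ≈ n/birth-rate), a 3-state Mk lifestyle history whose default
rates yield roughly one-third fully fossorial tips in several independent
origins (histories are redrawn until at least two origins with ≥ 2 tips
each and ≥ 2 tips per lifestyle class exist, so downstream tests are
well-posed on every seed), and state-switching Ornstein–Uhlenbeck traits.
OU transitions are sampled exactly per constant-regime segment
(x' = θ + (x − θ)e^{−αΔt} plus the exact stationary-approach variance), so
there is no integrator error and α = 0 reduces identically to BM.  Default
optima place fully fossorial taxa at high compactness (96 %), small
diameter (3.5 mm), elongate crania and low rfp, with pull α ≈ 1.5–2 per
unit time against a tree depth of ≈ 4–5; a pure-BM control trait carries no
lifestyle dependence and anchors specificity checks.  Section masks are
48×64 bars (pixel size 0.02 mm) whose shell thickness encodes the planted
thickness and whose interior is excavated pixel-by-pixel, never touching
the boundary, until the realised porosity matches the per-section target;
the realised values are the ground truth.  A ≥ 6 px shell floor keeps the
lowest compactness targets excavatable.

What passing tests show: the measurement chain recovers planted section
compactness exactly and planted overlap/rfp/dia/elo through the specimen
table; the inference chain detects the planted lifestyle signal and
convergence and stays quiet on the neutral control.  What they do not
show: robustness to segmentation noise, partial preservation, scan-
resolution heterogeneity, or real suture geometry — the bar silhouettes
are deliberately simple, and fossil (non-ultrametric) tips are not
generated by default.

## Numerical choices and scaled-down study conditions

* GLS solves use Cholesky factorisations; for ultrametric trees the λ
  profile likelihood uses a one-time eigendecomposition of V so each λ
  evaluation is O(n).
* Mk optimisation is Nelder–Mead on log rates, clipped to e^±... bounds
  wide enough that an effectively infinite rate (signal-free character) is
  representable without overflow.
* Uniformization caps the jump count at λ_pois + 10√λ_pois + 10 (≥ 20);
  the tail mass beyond the cap is renormalised away.
* The minimum-area ellipse is inflated by the largest focal-point Mahalanobis
  excess so floating-point support points are never excluded; fewer than
  three non-collinear focal points fall back to a padded bounding ellipse,
  flagged on the result.
* p-values use (b + 1)/(n + 1) with ≥ ties throughout.
* Test-suite problem sizes: λ recovery on a 200-tip tree × 200 replicates;
  Mk rate recovery on 300 tips × 100 replicates; ANOVA type-I calibration
  on 1 000 null datasets × 500 permutations (50 tips); C1/C5 null
  calibration on 300 datasets × 300 simulations (99 tips); the end-to-end
  study on 20 replicates of the generator defaults with 300 permutations/
  simulations per replicate.  These are the package's desk-scale study
  conditions; full-scale defaults (10 000 permutations and maps, 30 000
  simulations) remain the pipeline defaults.

## Known limitations

* C5 is an integer count, so its simulation p-value is discrete; under the
  (b + 1)/(n + 1) rule with ≥ ties it is conservative and its null
  distribution carries atoms (notably at p = 1).  A continuous-uniformity
  test on those p-values will reject on discreteness alone; calibration
  should be judged by validity (P(p ≤ α) ≤ α), which holds.
* C5 has little power when the focal set comprises few large clades: the
  observed count then nearly equals the number of clades, which BM nulls
  reproduce.  Power comes from many scattered entering lineages.
* The RRPP implementation covers the single-factor and single-covariate
  designs used here, not general multi-term models.
* Two-block PLS r is not invariant to duplicating a predictor column (the
  coefficient-norm constraint reweights); it is invariant to orthogonal
  rotation of a block, which is the property the tests pin down.
* Profile positions accept either 3-D polyline or projected landmark
  coordinates; the choice is the caller's and is not auto-detected.
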