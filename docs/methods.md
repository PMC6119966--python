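# Methods

## Scope and simulation model

All protocols run inside one process: "sites" are data containers, the
"network" is a function-call graph, and every payload that would cross a
real network is appended to a `MessageLog` with its exact size in real
scalars. The aggregator is one distinguished site, not a privileged
master; it may hold data of its own. Rounds are synchronous. No raw data
rows are ever concatenated across sites outside the pooled oracle paths,
which exist precisely to be compared against.

Payload accounting counts matrix entries, not bytes, because the
closed-form communication costs are naturally stated in matrix dimensions:
single-shot uploads (d+1) weights + 1 sample count per site; the
normal-equation variant uploads (d+1)² + (d+1) scalars per site (one Gram
matrix and one moment vector — the per-sample factor sometimes quoted for
this step does not apply, since the Gram matrix is uploaded once, not per
sample); group ICA moves d·r + r² scalars per non-aggregator site; each
decentralized K-Means iteration uploads (feature size)·k scalars per site.
For the audit conventions: a leaf site's traffic is what it sent plus what
it received from the aggregator; an intermediate site in the PCA peer
chain is charged only for the package it forwards, matching how the
closed-form totals are quoted. The aggregator broadcast is implemented to
the s−1 other sites; the printed aggregator-side total r²·s is kept
verbatim in `predicted_dgica_bandwidth` and interpreted as charging one
broadcast per consortium site.

## Decentralized regression

The model is y ≈ wᵀx + b with the intercept appended as the last design
column. The objective is the plain sum of squared errors, which is
additive across sites, so the pooled gradient is the exact sum of local
gradients; the weighted-mean (mean-squared-error) form has the same
minimizer and is not used. Site effects enter as S−1 indicator columns
(reference = first site) in the pooled, normal-equation, and multi-shot
designs; they are excluded from single-shot local designs, where an
indicator would be constant and the local problem rank-deficient.

**Normal-equation variant.** Summing X_jᵀX_j and X_jᵀy_j reproduces the
pooled cross-products exactly, so the solution, and all statistics
derived at it, are partition-invariant to floating-point accuracy. A
condition-number guard (10¹²) raises on global collinearity.

**Multi-shot (Adam).** Two choices matter and both are this package's own:

1. *Standardization round.* Covariates like age-in-years make the raw
   least-squares Hessian extremely ill-conditioned, which no first-order
   method handles well. One extra aggregation round therefore collects
   per-column sums and sums of squares (2(d+1) + 2V scalars per site,
   logged) so each site can standardize its design columns and response
   scales identically; fitted weights are mapped back to the raw scale in
   closed form. This adds one round of summary statistics and changes no
   estimand.
2. *Plateau-annealed Adam.* Learning rate 0.05, β₁ = 0.9, β₂ = 0.999,
   ε = 1e-8. With a full deterministic gradient, constant-rate Adam
   settles into a limit cycle whose amplitude scales with the learning
   rate and never reaches a tight gradient tolerance, so the rate is
   halved whenever the gradient infinity-norm has not improved by 10% in
   50 consecutive iterations. Stopping: gradient infinity-norm ≤ 1e-6 (in
   the standardized problem) or maximum weight change ≤ 1e-9; hard cap
   10000 iterations, after which the result is flagged non-converged.
   Weights start at zero unless a warm start is supplied. At the standard
   study scale (150 subjects, 200 voxels, 6 parameters) convergence takes
   roughly 400–900 rounds and lands within ~1e-7 of the pooled solution.

**Inference.** R² is computed from locally accumulated SSE and SST about
the globally aggregated mean (two rounds); t values use the standard OLS
sampling variance σ̂²·[(Σ_j X_jᵀX_j)⁻¹]_mm with σ̂² = SSE/(n − d − 1) and
two-tailed p from the Student-t survival function. No multiple-testing
correction is applied; maps report raw signed −log10 p. Saturated fits
(n = d + 1) return NaN inference rather than failing the whole fit.

## Voxelwise maps

All voxels of a site share one design, so per-site Gram matrices are
computed once and every estimator vectorizes over response columns; this
is algebraically identical to looping voxels. Unmasked or degenerate
voxels carry NaN in the output grids. Volumes are written in the input
grid's affine; no resampling is performed. The signed significance map is
−log10(p)·sign(t), with sign(0) = 0.

## Decentralized group ICA

Subject reduction is temporal PCA with whitening: the voxels × N_i matrix
is column-centered and its top-k1 left singular directions are scaled to
unit variance across voxels. Site blocks are the column-wise (temporal)
concatenation of their subjects' reductions. The global PCA chain carries
a d × r package of singular-value-scaled eigenvectors from site to site,
stacking and re-truncating at rank r per hop; with low-rank-plus-noise
data the dominant subspace survives the truncations, and the final
package is re-orthonormalized into V (r × d). SVD signs are fixed
deterministically (largest-magnitude entry positive) so runs are
reproducible.

Infomax ICA uses the logistic nonlinearity with natural-gradient block
updates (block size max(8, ⌊√d⌋)), a seeded sample-order shuffle per
pass, and learning-rate annealing (×0.9) when the angle between
successive weight updates exceeds 60°; it stops when the weight change
drops below 1e-7 or after 512 passes, and raises if weights blow up. The
logistic score targets super-Gaussian sources, appropriate for sparse
spatial maps. The estimated group maps are stored as Â = (W·Z)ᵀ (d × r,
Z the whitened eigenvectors). ICA's sign and permutation indeterminacy is
resolved only at comparison time by Hungarian matching on absolute
Pearson correlation — never inside the fit.

Back-reconstruction is the standard two-step spatio-temporal regression:
time-courses from regressing the subject data on Â, then subject maps
from regressing the data on those time-courses.

## Decentralized dFNC

Cleaning drops the first 2 scans, projects out the 24 motion regressors
plus an intercept, and spline-interpolates spikes (framewise displacement
strictly above mean + 2.5 sd; natural cubic splines through the good
timepoints, exact on cubic signals). Windows are rectangular, stride 1,
length w = 22 at full scale, giving T − w windows per subject (162 scans
→ 140 windows on the raw series; the pipeline windows the cleaned
160-point series, giving 138). Features are the strict upper triangle of
each window's sample covariance — under correlation distance the constant
diagonal is uninformative, so feature size is r(r−1)/2 rather than r²;
the communication audit accounts for this explicitly.

Exemplars are windows at strict interior local maxima of the per-window
variance of connectivity across component pairs (computed on covariance
entries); a monotone or constant series falls back to the single
global-maximum window. Decentralized K-Means assigns locally, uploads
per-cluster means and counts, and merges by count-weighted averaging —
exactly the pooled Lloyd update, so a single-site run is
assignment-identical to Lloyd's algorithm. Empty clusters are reseeded
from the globally farthest point (one extra logged broadcast).
Convergence is a full round with unchanged assignments, capped at 1000
iterations. Stage 1 runs 200 seeded initializations (k exemplar windows
drawn uniformly from the decentralized data; child seeds spawned from one
master seed) and keeps the run with the best silhouette under the same
correlation distance; stage 2 clusters all windows from those centroids.

## Synthetic generators

The regression fixture draws, per site, age ~ U(18, 65) and Bernoulli(½)
diagnosis and gender, applies planted N(0, 1) per-voxel coefficients, and
adds a site offset and unit Gaussian noise. Defaults — 3 sites × 50
subjects, 200 voxels — keep per-voxel statistics stable at interactive
runtimes. With site indicators in the design, the noiseless fixture is
recovered exactly.

The functional fixture mixes r = 5 sparse Gaussian blobs on a 10 × 10 × 5
grid through per-subject component time-courses drawn segment-wise from
k = 3 planted covariance templates (random low-rank-plus-identity,
rejection-sampled until all pairwise correlation distances are ≥ 0.5),
with dwell times uniform on 40–70 scans (≥ one window), T = 162, additive
white noise, a smooth 24-column motion table, and a framewise-displacement
series with planted spikes that also perturb the time-courses. Everything
is a pure function of the seed.

What the generators do *not* emulate: hemodynamics, spatial
autocorrelation of noise, scanner- or site-specific artifacts, realistic
gray-matter value ranges, or subject-level variability in the spatial
maps. Passing tests therefore demonstrate protocol correctness —
decentralized = pooled, planted structure recovered — not robustness to
real acquisition physics.

## Known limitations

- Window-level state labels are intrinsically ambiguous near state
  transitions: a 22-scan window straddling a switch has mixed covariance
  and no single true label. Scored against majority-rule window truth at
  the default conditions, state-label accuracy is typically 0.80–0.92
  across generator seeds (0.92 at the default seed); restricted to pure
  windows it is typically 0.88–0.99. Longer dwells or more separated
  templates would raise it, shorter windows would lower it.
- Constant-rate Adam (no anneal) does not reach the gradient tolerance on
  the raw-scale problem; the standardization round and plateau anneal
  described above are required for the multi-shot ↔ pooled equivalence to
  hold at tight tolerances.
- The global PCA chain is exact only when the data's rank-r dominant
  subspace is well separated from the residual; heavy truncation at
  intermediate hops of genuinely high-rank data loses variance (as any
  two-stage PCA does).
- Asynchronous updates, fault tolerance, encryption, and differential
  privacy are out of scope; the message log measures information volume,
  not security.
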