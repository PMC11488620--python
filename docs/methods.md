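# Methods

## Model

Resting-state BOLD at voxel v is modelled as
`y_v(t) = (h * s_v)(t) + ε_v(t)`, where `s_v` is a piecewise-constant
*activity-inducing* signal, `h` a canonical double-gamma haemodynamic
response (peak 6 s, undershoot 16 s, undershoot ratio 1/6, unit peak,
sampled at the TR; default TR 2 s, kernel length 32 s), and `ε_v` white
Gaussian noise. The *innovation* signal `u_v = D s_v` (first difference)
is sparse: its spikes are the onsets and offsets of network activations.
Clustering the innovation maps of significant-transient volumes across
subjects yields K spatial networks (iCAPs); per-subject back-projection of
those maps into the activity signals yields network time courses, whose
thresholded trains define the temporal properties analysed downstream.

## Deconvolution

Objective per voxel: `½‖y − H s‖² + λ‖D s‖₁`.

* Solver: monotone FISTA on the analysis form. The proximal operator of
  `λ‖D·‖₁` is exact 1-D total-variation denoising, computed by the
  taut-string construction (greedy segment growing through a tube of
  half-width λ around the running sum, pinned at both ends). The
  implementation is verified in the test suite against an independent
  oracle — the box-constrained dual least-squares problem solved with
  `scipy.optimize.lsq_linear` — to 1e-8. Momentum restarts whenever any
  voxel's objective would increase and increases are never accepted, so
  objective traces are non-increasing per voxel by construction.
* Why analysis form: re-parametrising by cumulative sums (the synthesis /
  LASSO form) is mathematically equivalent but multiplies the Lipschitz
  constant by roughly `O(T²)`, and at tight tolerances the iteration count
  became four orders of magnitude larger. With the taut-string prox the
  gradient step involves only the convolution operator (`L = ‖H‖²`) and a
  few hundred iterations reach support-exact solutions on noiseless input.
* Regularisation: `λ_v = c · σ̂_v · √T`, with
  `σ̂_v = MAD(Δy_v)/(√2·0.6745)`. σ̂ is floored at `1e-3·SD(y_v)` because
  the sampled kernel has `h(0) = 0`, so with exactly noiseless input the
  unpenalised problem is underdetermined and a vanishing λ would admit
  dense solutions. The scale defaults to `c = 0.5`: on phantoms at the
  generator's noise level, `c = 1` visibly over-shrinks short activation
  blocks (duration recovery correlation drops from ≈0.95 to ≈0.75), while
  `c = 0.5` keeps edges within ±1 volume; both remain configurable.
* Boundary: the first 3 volumes of a deconvolved session are flagged
  unusable (in the propagated scrub mask). The haemodynamic response of
  activity preceding the series leaks into them, so the recovered activity
  there reflects an arbitrary initial condition; leaving them in biases
  course normalisation and durations.

## Transient selection and clustering

* A volume is a transient if its count of voxels with |innovation| above
  the subject's pooled 95th-percentile threshold is at least 1% of the
  mask (per-subject thresholding by default; a pooled-across-subjects
  option exists, since either reading is plausible).
* k-means uses distance `1 − |cos|`; a frame may be sign-flipped to match
  its centroid, with the flip recorded. Centroids are normalised
  sign-aligned means; k-means++ seeding adapted to this distance; 20
  replicates, best by within-cluster dispersion; exact distance ties go to
  the lowest cluster index. The 6-frame/K=2 case is checked against
  exhaustive enumeration of all two-part partitions, with each partition
  scored by alternating sign/centroid optimisation to a fixed point (the
  same centroid rule the solver applies).
* Consensus clustering: for each K, 30 resamples of 80% of frames;
  `consensus[i,j]` = co-clustered / co-sampled; never co-sampled pairs are
  missing and excluded from means; the selected K maximises the mean over
  clusters of within-cluster mean consensus (ties go to the smaller K).
* iCAP maps are means of sign-aligned member frames, z-scored over the
  mask. A region report lists atlas regions with more than 20% of voxels
  at |z| > 2 when a region labelling is supplied.

## Time courses and temporal properties

* Back-projection: at each time point, OLS of the activity map (over
  mask voxels) on the K z-maps, both mean-centred over voxels. This is a
  deliberate simplification of the full transient-informed regression
  with innovation-consistency constraints; it is exact for the generator's
  linear forward model. Near-collinear map pairs (condition number of the
  Gram matrix above 1e8) raise an error naming the offending pair.
* Activation trains: |z| > 1 on the z-normalised course (normalisation
  statistics over usable volumes only), signed by the course sign;
  scrubbed and boundary volumes forced to zero. The threshold value 1 is
  the framework convention; it is configurable.
* Total duration = 100 × active / non-scrubbed volumes. Occurrences =
  maximal same-sign runs (a sign change without a zero gap starts a new
  block; zero-gaps introduced by scrubbing split blocks — a documented
  consequence of masking rather than deleting volumes). Coupling and
  anticoupling are Jaccard fractions with the union of active time as
  denominator, zero when the union is empty. Occurrences are computed per
  iCAP (width K), not per pair: the pair wording in the source material
  conflicts with the framework's prior usage, and the per-iCAP reading is
  implemented.

## Reliable change and group statistics

* `RCI = d_i / SEM_d`, `d_i = after − before`. `SEM_d = SD_baseline·√2·√(1−r)`
  (the Jacobson–Truax difference-score form). The reliability r may be
  supplied (normative test–retest values); otherwise it is estimated as
  the in-sample pre/post Pearson correlation, clipped into [0, 0.99] with
  a warning — negative correlations occur routinely for noisy dynamic
  metrics at n = 32 and would otherwise make `SEM_d` imaginary.
* Group comparisons use the pooled (equal-variance) two-sample t: the
  published degrees of freedom (54 = 32 + 24 − 2) imply pooled rather than
  Welch. Chi-square is Pearson without continuity correction, df = 1.
* The pre/post model is a random-intercept model of score on time; on
  balanced two-timepoint data its time effect is numerically the paired
  t-test, which is how it is computed; an explicit MixedLM route is
  provided and the identity is asserted in a test.
* BH-FDR via `statsmodels.stats.multitest`, flagged at q < 0.1.

## PLSC

Columns of X and Y are z-scored; `R = XᵀY/(n−1)`; SVD `R = U S Vᵀ`.
Permutation: rows of X permuted against Y, p per component =
`(1 + #{s_perm ≥ s_obs})/(n_perm + 1)`, singular values compared rank by
rank without Procrustes alignment (the simplest defensible scheme; the
published analysis may have used an aligned variant, which primarily
affects components beyond the first). Bootstrap: subjects resampled with
replacement; each bootstrap component is sign-aligned to the original via
salience dot products; loadings are correlations of original variables
with their own block's component scores; a loading is *robust* when
|bootstrap mean| / bootstrap SD ≥ 2 (threshold configurable — the source
figure does not define "robust"). Resamples with a zero-variance column
are redrawn and counted. Defaults: 1000 permutations, 500 bootstraps,
seed mandatory.

## Synthetic cohorts

The generator emulates the study's statistical structure, not its anatomy:

* 32 subjects × 2 sessions; 8 contiguous network blobs grown by seeded
  BFS on a 12×12×12 lattice (~1.7k voxels; experiments and the acceptance
  script use 9×9×9 so that 10 replicate cohorts run in minutes — problem
  sizes chosen for desk-scale validation); pairwise blob overlap capped by
  `overlap_frac` (default 0).
* 105 volumes at TR 2 s; the first 5 are dropped at scrubbing. Block
  trains have exact integer-volume durations (recorded bookkeeping equals
  recounts by construction), lengths 4–10 volumes, and at least 3 silent
  volumes between blocks so that distinct activations remain resolvable
  after haemodynamic blurring at TR 2 s.
* Baseline durations are uniform in 10–25% of volumes per network —
  the range reported for iCAP engagement in prior applications of the
  framework. The planted effect adds `δ_s ~ N(10, 3)` percentage points
  (floored at 0) to 4 of the 8 networks in session 2. Block *counts* are
  held fixed within subject-network across sessions, so the shift changes
  durations only: occurrence counts carry no planted structure by
  construction, and coupling changes only through incidental overlap.
* Gaussian BOLD noise, SD 0.5 relative to unit activation amplitude;
  random-walk motion with 2% displacement spikes, FD threshold 0.5 mm,
  head radius 50 mm.
* Clinical block: five change scores; three carry
  `Δscore = −0.8 · mean(δ_s) + N(0, 2)` (negative: difficulty scores fall
  as network engagement rises), two are pure noise; gestational age
  ~N(29.1, 2.0) weeks and age ~N(145.8, 14.8) months complete the 7-column
  clinical matrix of a 32-subject cohort.

What passing tests show — and do not. The generator's forward model is the
model the deconvolution inverts, with stationary Gaussian noise, a known
HRF, binary network memberships and no spatial autocorrelation,
physiological confounds, or HRF variability. Recovery statistics (duration
r ≈ 0.95, map Dice ≈ 1, the PLSC significance pattern) therefore validate
the implementation and the statistical chain, not performance on real
fMRI, where HRF mismatch and structured noise will degrade all stages.

## Numerical choices and degenerate inputs

* FISTA: max 500 iterations (250 in the scaled experiment configs), stop
  when every voxel's relative objective change is below 1e-5 (1e-6 in
  experiments).
* Exact tie-breaks: k-means assignment → lowest cluster index; consensus
  K tie → smaller K; sign 0 treated as +1.
* All-zero innovation input yields an empty transient set with a warning,
  not an error. All-scrubbed sessions raise. Zero-variance courses yield
  flagged NaNs in static correlations. Zero-variance brain features are
  dropped from PLSC blocks (their RCI is undefined).
* Determinism: every stochastic step takes a seed or a `numpy` Generator;
  pipeline reruns with the same config are byte-identical for tabular
  outputs.

## Known limitations

* The deconvolution omits the spatial (structured-sparsity) term and any
  per-subject HRF estimation of the original total-activation framework.
* Per-timepoint OLS back-projection ignores the innovation-consistency
  constraints of the full transient-informed regression.
* The consensus-K criterion uses mean within-cluster consensus only; no
  CDF-area or PAC variants.
* Couplings inherit a weak dependence on planted duration shifts (longer
  blocks overlap more); in the shipped conditions this stays below the
  detection threshold of the PLSC in ≥ 8/10 runs, mirroring the emulated
  study's null results, but it is a structural property of Jaccard
  measures, not an absence of any effect.
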