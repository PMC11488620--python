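# icapkit

Dynamic functional connectivity for paired (pre/post-intervention)
resting-state fMRI via **innovation-driven coactivation patterns (iCAPs)**,
with the downstream statistics used to relate brain-dynamics change to
behavioural change: reliable change indices and partial least-squares
correlation.

The package is aimed at researchers who want a tested, self-contained
implementation of this analysis chain — and a synthetic-data generator
with planted ground truth, so every stage can be validated quantitatively
rather than by eyeballing brain maps.

## The analysis

1. **Sparse hemodynamic deconvolution** (`icapkit.deconv`). Each voxel's
   BOLD series `y` is modelled as the causal convolution of a
   piecewise-constant activity-inducing signal `s` with a double-gamma
   haemodynamic response `h`. The stage solves

   `min_s  ½‖y − H s‖² + λ‖D s‖₁`

   (`D` = first difference), so the *innovations* `u = D s` are sparse
   spikes marking activation onsets and offsets. Monotone FISTA with an
   exact taut-string total-variation proximal step; `λ = c·σ̂_v·√T` with a
   robust (MAD) noise estimate per voxel.
2. **Transient clustering** (`icapkit.icaps`). Volumes with enough
   suprathreshold innovation activity are pooled across subjects and
   clustered with a sign-invariant cosine k-means (a deactivation transient
   is the same network as an activation transient). The number of clusters
   K is chosen by consensus clustering; cluster means of sign-aligned
   frames, z-scored over the mask, are the iCAP maps.
3. **Temporal properties** (`icapkit.tempmetrics`). Per subject-session,
   iCAP time courses are recovered by per-timepoint regression of the
   activity maps on the K z-maps; thresholding at |z| > 1 gives signed
   activation trains, from which follow the **total duration** (% of
   non-motion volumes active), **occurrences** (number of activation
   blocks), and **coupling/anticoupling** (Jaccard fraction of time two
   iCAPs are jointly active with the same/opposite sign), plus static
   inter-iCAP correlations.
4. **Reliable change** (`icapkit.change_stats`).
   `RCI = (after − before) / SEM_d`, with `SEM_d = SD·√2·√(1−r)`; also
   pooled two-sample t and chi-square cohort comparisons, OLS group models,
   random-intercept pre/post models, and Benjamini–Hochberg FDR.
5. **PLS correlation** (`icapkit.plsc`). statsmodels-style: build
   `PLSC(X, Y)` from the clinical block (RCIs + gestational age + age at
   assessment) and a brain block (duration / occurrence / coupling /
   anticoupling RCIs), call `.fit()`, get a `PLSCResults` with singular
   values, permutation p-values per latent component, bootstrap loading
   means/SDs and robustness flags, and a `summary()`.

The synthetic generator (`icapkit.synth`) emulates the study design: 32
subjects × 2 sessions, 8 networks on a 3-D lattice, block activations
convolved with the HRF plus Gaussian noise, motion spikes with FD-based
scrubbing, a planted *increase in activation duration* for 4 of the 8
networks in the second session, and clinical change scores linearly coupled
to that planted shift.

## Worked example

```python
import numpy as np
from icapkit import synth, deconvolve_session, scrub, tempmetrics
from icapkit.experiments import run_cohort_analysis, small_config

res = run_cohort_analysis(small_config(seed=1))
print("duration recovery r per network:", np.round(res.duration_r, 2))
print("LC1 permutation p:", {k: round(v, 3) for k, v in res.lc1_p.items()})
print(res.plsc_results["duration"].summary())
```

prints (seed 1):

```
duration recovery r per network: [0.99 0.99 0.98 0.99 0.98 0.99 0.98 0.95]
LC1 permutation p: {'duration': 0.005, 'occurrences': 0.632, 'coupling': 0.189, 'anticoupling': 0.96}
Partial least-squares correlation
  n subjects: 32   X: 7 cols   Y: 8 cols
  LC   singular   %cov     perm p
   1     1.9523    77.9   0.0050
   2     0.8045    13.2   0.0697
   3     0.4110     3.5   0.9303
   ...
```

Reading: the per-network activation durations recovered by the full
deconvolve → cluster → back-project chain correlate at r ≈ 0.95 with the
planted durations; the PLSC linking clinical change to duration change is
significant (p = 0.005 at 200 permutations, i.e. the floor 1/201), while
the occurrence, coupling and anticoupling analyses — which carry no planted
structure — are not.

A file-based pipeline with the same stages is available from the shell:

```bash
icapkit run --config examples/demo.yaml       # simulate → deconvolve → icaps
                                              # → metrics → rci → stats → plsc
icapkit simulate --config examples/demo.yaml  # or stage by stage
```

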