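# Methods

## The index

The fractal dimension index (FDI) treats cortical activity as a
spatiotemporal point process. Given a source model (N dipole positions,
each labelled with one of five resting-state networks or left
unassigned) and an N × T matrix of signed source currents at sampling
rate fs, the pipeline is:

1. **Thresholding.** For each source, θᵢ = mean + sample standard
   deviation (divisor T − 1) of |xᵢ(t)| over the *whole epoch*; a sample
   is an activation iff |xᵢ(t)| > θᵢ (strict). The rule is equivariant
   under positive rescaling of any source's series, so current units are
   irrelevant. Binarization is whole-brain; network analyses restrict the
   mask afterwards. An optional `window` scope recomputes thresholds
   inside each window for sensitivity analyses; it is not the default
   because thresholds are conceptually epoch-level statistics and
   per-window statistics of 1-s slices are much noisier.
2. **Windowing.** Non-overlapping 1-s windows (⌊T/W⌋ of them, trailing
   remainder dropped), W = round(fs). Windows are independent given the
   thresholds.
3. **Voxelization.** Source positions are mapped to a G³ grid (G = 64 by
   default, a power of two) inside an axis-aligned bounding box computed
   once per subject from *all* source positions and padded by a relative
   1e-9, so grids are comparable across windows and networks and the
   construction is invariant under translation and uniform scaling of the
   coordinates. For the 4-D cloud the window's local time axis is
   quantised to G bins (floor rule), giving an isotropic G⁴ index space.
4. **Dimensions.** 3DFD(t): box-counting dimension of the active cloud at
   sample t. 4DFD: box-counting dimension of the window's 4-D cloud.
   HFD(3DFD): Higuchi dimension of the window's 3DFD series.
   FDI = 4DFD × HFD(3DFD).
5. **Aggregation.** Subject × region FDI = mean over non-degenerate
   windows; group trend curves average each window index over a group's
   subjects.

### Box counting

N(ε) is the number of ε-sided hypercubes (nested dyadic partitions of the
grid; powers of any base that divides the side are accepted) containing at
least one occupied cell; the dimension is the OLS slope of log N(ε)
against log(1/ε) over all scales {1, 2, …, G/2}, with R² reported for
auditing. No scale-range pruning is applied. Because coarsening by factor
b merges at most b^d boxes, every pairwise slope — and hence the OLS
slope, a convex combination of them — lies in [0, d]; the bounds
3DFD ≤ 3 and 4DFD ≤ 4 are therefore theorems of the implementation, not
empirical observations. Counting is done sparsely (unique coarse cell
indices of the occupied set), with a deliberately naive loop-over-boxes
oracle retained for testing. An empty cloud has dimension 0 and is
flagged degenerate.

### Higuchi dimension

The standard construction: for lags k = 1..kmax and offsets m = 1..k the
normalised curve length L_m(k) is accumulated from |X(m+ik) − X(m+(i−1)k)|
with the usual (N−1)/(⌊(N−m)/k⌋k²) normalisation; L(k) is the mean over
offsets and the dimension is the slope of log L(k) vs log(1/k), clamped
to the theoretical range [1, 2] (the raw slope is retained). kmax
defaults to 8: with 500-sample windows this keeps ≥ 61 increments per
offset and a stable regression; it is configurable. A constant series
(zero curve length at every lag) returns 1 with a degenerate flag; lags
with zero mean length on non-constant input (pathological periodic
series) are dropped from the regression.

### Degenerate windows

The thresholding rule does not guarantee activations at every sample, and
a window can be entirely event-free (common for very smooth dynamics).
Samples with no activations contribute 3DFD = 0; windows with no events
get FDI = 0, are flagged, and are excluded from the subject average
(with a warning reporting the count). This convention is explicit because
the empty case has no canonical definition.

## Statistics

* **Quade rank ANCOVA.** Response and covariates are ranked across all
  subjects (average ranks for ties); response ranks are regressed on
  centred covariate ranks by OLS; the residuals are compared between
  groups by one-way ANOVA with F on (g − 1, n − g − c) degrees of
  freedom, c being the matrix rank of the covariate block (so constant
  covariates consume no df and the test reduces exactly to one-way ANOVA
  on ranks). The df convention is validated by null simulation: at the
  study-sized design (20 vs 11, three covariates) the empirical type-I
  error at α = 0.05 is 0.048 over 1,000 replicates. Covariate coding:
  education Primary/Secondary/High → 1/2/3, sex M/F → 0/1.
* **Spearman + Bonferroni.** ρ from ranked Pearson; exact two-sided
  permutation p for n ≤ 9 (full enumeration), t approximation otherwise;
  family size = number of (FDI, score) pairs actually tested; both raw
  and adjusted p are reported. Clinical-scale correlations are run on the
  patient rows only, since controls have no such scores.
* **Mann–Whitney U / χ².** U counts pairs won by the first sample plus
  half-ties; exact enumeration when n₁n₂ ≤ 400 and tie-free, tie-corrected
  normal approximation otherwise. χ² without continuity correction.
* **ROC/AUC.** Score = −FDI with the patient group as the positive class
  (orientation fixed: low FDI predicts patients); trapezoidal AUC with an
  internal assertion of the identity AUC = U/(n₁n₂) including half-credit
  for ties.

## Synthetic data

The generator emulates the statistical structure the pipeline needs to be
testable, not the biophysics of EEG:

* **Geometry.** Sources are uniform on a 70-mm sphere surface — a
  cortex-like *sheet*, so a fully active brain reads as quasi-2-D
  (3DFD ≈ 2 at the full 15,002-source scale) and instantaneous clouds
  stay in the regime real source models produce. Networks are contiguous
  longitude wedges (15% of sources each by default, remainder
  unassigned).
* **Dynamics.** Each network (the unassigned remainder acts as its own
  group) carries a standardised fractional-Brownian-motion envelope,
  synthesised as cumulative exact-covariance fractional Gaussian noise
  (Davies–Harte circulant embedding; the theoretically nonnegative
  eigenvalues are clipped at round-off level if needed). The Hurst
  exponent H sets the envelope's roughness and is the complexity dial:
  the Higuchi dimension of an fBm trace is 2 − H, which also makes fBm
  the estimator's oracle.
* **Per-source offsets.** Each participating source sees the envelope
  shifted by a time-constant Gaussian offset (SD `noise_sd`). This is
  deliberate: offsets stagger the levels at which sources cross their
  thresholds, so the active cloud waxes and wanes *gradually* with the
  envelope and the 3DFD curve inherits the envelope's roughness. (With
  identical series plus white noise the network activates in lockstep,
  the 3DFD curve is near-binary, and — because the Higuchi estimate is
  amplitude-free — any residual flicker pushes it toward 2 for smooth and
  rough envelopes alike, destroying the complexity contrast.) In the
  `noise_sd = 0`, full-extent limit all of a network's sources carry an
  identical series. Sources outside the `activation_extent` fraction stay
  silent, making the spatial extent of activation controllable.
* **Cohorts.** Patients' envelope Hurst exponent is shifted by
  `group_effect` (+0.4 by default: smoother, less complex dynamics);
  subjects get an individual jitter (SD 0.08 — large enough that
  between-subject complexity differences dominate the windowing noise of
  a short record, small against the group shift). Covariates and
  cognitive scores are drawn from group profiles matching a typical
  schizophrenia/control study (ages ~36/41, male-skewed patient group,
  SCIP-S-like subscale means). Synthetic PANSS scores increase with the
  subject's Hurst exponent, building in the negative FDI–severity
  correlation the statistics layer must be able to recover; PANSS columns
  are absent for controls.

What passing tests on this generator show: the pipeline's bookkeeping,
bounds, determinism, estimator accuracy on analytic fixtures, and its
ability to recover group differences and monotone score links that are
genuinely present. What they do not show: performance on real EEG source
currents, whose spatial correlation structure, 1/f spectra, artifacts and
inverse-solution smoothing the generator does not model.

## Problem sizes and defaults

| Parameter | Default | Notes |
|---|---|---|
| grid side G | 64 | resolves ~15k cortical sources without saturating; 4-D counting stays cheap via sparse indices |
| box scales | 1..G/2 dyadic | all scales enter the fit; R² reported |
| kmax | 8 | ≥ 61 increments/offset at 500-sample windows |
| window | 1 s | non-overlapping tiling |
| threshold scope | epoch | `window` available |
| synthetic scale | 2,000 sources, 30 s @ 250 Hz | keeps a 10-subject, 6-region run ≈ 1–2 min |
| test scale | 400–600 sources, 10–15 s @ 125 Hz | keeps the suite ≈ 1 min |

Full study scale (15,002 × 75,000 at 500 Hz, 150 windows) is supported by
the same code paths; per-subject cost grows linearly in T and in the
number of active events.

## Known limitations

* Box-counting estimates at desk scale sit below the 3–4 band reported
  for dense full-scale recordings: with hundreds rather than thousands of
  active sources, fine scales saturate and the fitted slope drops. The
  bounds (≤ 4, ≤ 8) hold regardless.
* The OLS fit uses all dyadic scales; no automatic scaling-region
  detection is attempted (R² is exposed instead).
* Quade's procedure is implemented in its regression-on-ranks form; other
  software may use slightly different denominator df. The choice here is
  documented above and calibrated by simulation.
* The synthetic cohort is a statistical stand-in, not a physiological
  simulation (no volume conduction, no inverse-model leakage).
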