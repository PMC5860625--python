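# Methods

## Model

A peak histogram `h` (per-peak ion counts for one spectrum) is modelled as

    m_i = Σ_k Q_k · P(i|k),   h_i ~ Poisson(m_i),  Q_k ≥ 0,  Σ_i P(i|k) = 1.

The components `P(·|k)` are shared across a corpus; the weights `Q` are per
spectrum. Because each component is a PMF, `Σ_i m_i = Σ_k Q_k` holds
identically and the maximum-likelihood weight total equals the observed
total. All quantities are in *events* (intensity divided by the detector
gain, the intensity units recorded per ion), which is what makes the
Poisson likelihood the right noise model.

### Estimation

Maximum likelihood by EM. With responsibilities
`r_ik = Q_k P(i|k) / m_i`:

* weights (per spectrum): `Q_k ← Σ_i h_i r_ik`
* components (training only): `P(i|k) ← Σ_s h_si r_sik`, renormalised.

Both updates derive from the complete-data likelihood of the multinomial
mixture with Poisson totals, so the corpus log-likelihood is non-decreasing
(asserted in tests). Components are initialised from the corpus-mean PMF
with multiplicative Gamma(5,1) jitter (a Dirichlet-style perturbation),
weights as equal shares of each spectrum total; everything is a
deterministic function of the seed. Convergence: relative log-likelihood
change < 1e-8 or 10 000 iterations.

Numerical choices:

* PMF probabilities are floored at 1e-12 during EM (avoids −∞ likelihoods)
  and snapped to exact zero below 1e-9 afterwards, so zero-structure
  criteria are meaningful.
* Fitted weights below 1e-9 of the spectrum total are snapped to zero:
  multiplicative EM approaches the non-negativity boundary geometrically
  and otherwise stalls at sub-event dust, which pollutes residual
  diagnostics (see Bland–Altman below).
* The weight covariance is the inverse observed Fisher information
  `I_kl = Σ_i h_i P(i|k) P(i|l) / m_i²` at the solution (pseudo-inverse
  with a warning when the condition number exceeds 1e12), inflated by the
  model χ²/dof when that exceeds 1 — an imperfect model under-reports its
  own noise — and never deflated below the Poisson floor.

### Model order

χ² per degree of freedom with
`dof = S·B − [K·(B−1) shared + K·S per-spectrum parameters]` and a
denominator floor of 1e-3. The selected order is the smallest K whose
best-of-restarts score is within 5 % (relative) of the best score over the
scanned range — the first K that reaches the minimum or its plateau. The
per-K model is the best of several seeded restarts *by likelihood* (using
the χ² minimum instead would bias the curve downward at larger K, where
restarts are more diverse). Overfit drift of χ²/dof past the true order
scales roughly as 1/S + 1/B, so the 5 % plateau tolerance presumes corpora
of the scale this method is used at (tens of spectra, ~50–100 retained
peaks); on much smaller problems the plateau rule will over-select.

### MAX SEP

ML component sets are linearly degenerate: recombinations spanning the same
fitted cone fit equally well. MAX SEP subtracts from each component the
largest multiple of every other component that keeps all probabilities
non-negative, renormalises, and sweeps until no pair changes (tolerance
1e-6 on the subtracted fraction, at most 100 sweeps). Pairs are visited in
descending order of total fitted weight (dominant structure first — the
order is otherwise immaterial to the fixed points but affects the path). A
subtraction that would leave less than 5 % of the target's mass is vetoed
to stop near-duplicates annihilating. Where the corpus weights remain
feasible in the new basis, the fitted span — and hence the refitted
likelihood — is unchanged; where they were infeasible (a spectrum needing a
negative coefficient in the degenerate basis), separation strictly improves
the fit. The simplicity report counts near-zero bins (< 1e-6) per component
and, for each ordered pair, bins where one component is near-zero while the
other exceeds its own mean bin probability.

### Class calibration

Components are labelled A, B or rejected. A component whose fractional
weight across the corpus has |Pearson r| < 0.2 with the true proportions is
rejected (contamination or class-ambiguous structure). Remaining components
are assigned by exhaustive search over A/B labellings (up to 10 candidates;
greedy by correlation sign beyond that), scoring each labelling by the
calibrated residual. Because the affine map can absorb a label swap, the
labelling is anchored so that class A is the side whose weight fraction
rises with the true fraction of A.

Calibration then fits per-component efficiency weights `w_k > 0`
(mass per detected event) and an affine map so that
`slope · [Σ_{k∈A} w_k Q_k / Σ_{k∈A∪B} w_k Q_k] + intercept` tracks the true
proportions in least squares. Optimisation is Nelder–Mead over
log-efficiencies (positivity by construction; the first component's
efficiency is pinned at 1 since the fraction is scale-invariant) with 10
seeded multistarts; the affine map is closed-form given the efficiencies.
`precision` is the sample standard deviation of the (unclipped) calibrated
residuals. Predictions are clipped to [0, 1] only at prediction time, with
the unclipped value retained; predicted errors propagate the weight
covariance through the ratio and the affine slope to first order.

When the ML solution splits one class across several near-collinear
components (which can genuinely have higher likelihood than the generating
structure — observed on the default synthetic corpus, where the
class-plus-contamination split fits +97 log units above the true
components), the *per-component* efficiencies along the degenerate
direction are not identifiable; the identifiable quantity is the
class-level effective efficiency `Σ_{k∈class} w_k Q̄_k / Σ_{k∈class} Q̄_k`,
which is what the recovery tests assert.

An ensemble mode fits the same spectrum under many independently trained
and calibrated models (50 in the original design) and reports the mean,
spread, median and best-by-precision answers, damping local-optimum
variability.

## Noise diagnostics

**Bland–Altman / power law.** One point per (spectrum, bin): expected bin
value (model prediction × gain) against residual (observed − expected,
× gain). Residual sample variance over 20 equal-count quantile bands is
regressed as `log Var = log a + b·log centre`; `b = 1` with `a =` gain is
the scaled-Poisson signature, `b = 0` the iid-Gaussian one. Bins expecting
fewer than 0.5 events are excluded: below ~1 event almost every draw is
zero, the empirical "variance" in such a band reflects the spread of the
means (∝ centre²) rather than Poisson noise, and those bands act as pure
leverage toward `b = 2`. With per-spectrum fitted weights the exponent on
truly Poisson corpora comes out slightly below 1 (≈ 0.95–0.98; fitted
parameters absorb part of the residual variance preferentially where
expectations are large).

**Pulls.** `(prediction − truth)/predicted error`, using unclipped
predictions; width uses the n−1 sample convention. Mean 0 means unbiased;
width 1 means errors are sized correctly. On clean two-class scaled-Poisson
corpora the width is ≈ 0.97. On corpora with contamination and degenerate
component splits the width drops to ≈ 0.8: the Fisher covariance charges
the poorly-determined degenerate direction to every prediction whose
efficiencies differ along it, and boundary spectra (0 % and 100 %) have
one-sided errors under the non-negativity constraint — both make the
predicted error conservative rather than optimistic.

## Preprocessing

* **Alignment**: resample onto the reference axis, maximise cross-
  correlation over integer steps within ±max_shift, parabolic sub-bin
  refinement, shift by interpolation, conserve resampled total intensity.
* **Baseline**: a peak mask from a morphological opening (window =
  `smoothness`, which must exceed the widest peak), dilated by an eighth of
  the window to cover flank tails; masked samples are bridged by
  interpolating the surrounding background, and the baseline is the rolling
  median of the bridged signal, lightly smoothed. The median of zero-mean
  background noise tracks the baseline itself, so background regions stay
  zero-mean and negative residuals are retained, not clipped.
* **Peak bins**: threshold the corpus-mean spectrum at `significance`
  (default 5) × a MAD-based noise estimate, grow runs outward at a lower
  hysteresis threshold, merge touching runs; bins are half-open `[low,
  high)` with intensity-weighted centroids; inter-peak gaps are discarded.
* **Integration**: sum intensity per bin, divide by gain, clip at zero.
* **Filtering**: reject spectra below/above total-count thresholds
  (low signal-to-noise / saturation); thresholds are configuration values
  with no universally correct defaults.

## Synthetic data

`make_class_pmfs` draws two class sub-spectra over 80 candidate bins in a
650–850 Da window (24 log-normal peaks each, 30 % of positions shared with
independent intensities) plus a 6-peak contamination PMF on its own
positions, then drops bins no component occupies — mirroring preprocessed
histograms, which keep only significant-peak bins. `generate_corpus`
realises the binary-mixture design: 11 proportions × 8 replicates, total
events uniform in 2 000–20 000 per spectrum (per-peak counts of order
10²–10³ at desk-top runtimes), class-B detection efficiency 0.5,
contamination level 0.05, independent Poisson draws per bin, gain recorded
so rendered intensities are `gain × counts`. `add_profile_artifacts`
renders a histogram as Gaussian peaks (σ 0.3 Da on a 0.05 Da axis) with a
smooth sinusoidal baseline, zero-mean Gaussian noise and a global m/z
jitter, exercising the full preprocessing path.

What the generator does *not* emulate: peak-shape variation and isotope
structure, suppression effects, correlated (non-independent) bin noise,
detector saturation, and baseline chemistry beyond a smooth curve. Passing
tests therefore demonstrate correctness of the estimation and error theory
under the model's own assumptions, not robustness to every instrumental
artefact of real spectra.

## Known limitations

* Weakly expressed components (e.g. few-percent contamination) may be
  absorbed into class components by an equally-likely or better ML
  solution; they are then handled by the rejection/efficiency machinery
  rather than recovered as separate sub-spectra.
* Fisher-information errors are asymptotic and unconstrained; at the
  proportion boundaries they overstate the spread of the constrained
  estimator (conservative).
* In-sample calibration precision is optimistic; `rank_and_calibrate`
  exposes the same convention for the peak-ratio benchmark so the
  comparison is like-for-like.
* The χ²/dof plateau rule assumes study-scale corpora (see above).
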