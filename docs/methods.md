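# Methods

## The problem

Power spectra of single-unit spike trains are distorted by the post-spike
*recovery period* (RP) — the interval of reduced spike probability that
follows every spike, whether from channel-level refractoriness or from
longer circuit- or pacemaker-driven pauses. Relative to the flat spectrum
of a rate-matched Poisson process, an RP produces a trough over the low
frequencies and elevated, ringing power at high frequencies; the
distortion grows with firing rate and RP duration. A significance test
that screens the (0, 100] Hz band against a flat baseline therefore
misses genuine oscillatory peaks sitting in the trough and flags
distortion-driven power elsewhere.

`spikespectra` implements two corrections and the machinery to compare
them:

* **ISI shuffling** — estimate the spectrum of the matched *renewal*
  process (same inter-spike-interval distribution, intervals drawn
  independently) by averaging Welch PSDs over ISI-permuted surrogate
  trains, and divide it out of the original PSD. This removes the RP
  contribution, but also removes any rhythmic information carried by the
  first-order ISI statistics — a real loss when firing is so sparse that
  spikes arrive about once per oscillation cycle.
* **Point-process residuals** — estimate the RP duration from the ISI
  distribution, fit a *bounded last-spike* Poisson GLM that models only
  the first `n_r_hat` ms of the post-spike hazard, and take the Welch PSD
  of the raw residuals. Only the RP-attributable variance is removed;
  longer-lag temporal structure survives into the corrected spectrum.

## Simulation model

Spike trains are generated as a discrete-time (1 ms bins, 1 kHz)
approximation of an inhomogeneous Poisson process. Per bin,

    p_spk(t) = p_SS(t) = p_base + p_osc * sin(2*pi*f_osc*t/1000)   if n > n_r
             = p_SS(t) * k^(n_r + 1 - n)                           if n <= n_r

where `n` is the latency (ms) since the last spike, `n_r` the RP duration
(ms) and `k` in [0, 1) the exponential recovery steepness (`k = 0` is an
absolute RP). `p_base` is the base rate expressed per bin (Hz/1000);
`p_osc = m * p_base` with modulation index `m` in [0, 1], so the rate never
goes negative and `p_spk` stays in [0, 1] provided `p_base + p_osc < 0.5`
(enforced). Each bin is an independent Bernoulli draw, so bins never hold
more than one spike (orderliness).

Choices the model statement leaves open:

* **Initial condition** — before the first spike the unit is treated as
  outside the RP (steady-state probability). After one ISI the process
  forgets the initial state, and every analysis window used here is far
  longer than one ISI.
* **Phase origin** — the sinusoid is evaluated at the 1-based ms bin
  label. No measured quantity depends on the phase origin.
* **Latency convention** — a spike in bin `t` gives latency `n = 1` at
  bin `t + 1`.

The generator emulates rate-modulated renewal-like firing only. It does
not produce burst firing (state-dependent RPs), 1/f-like aperiodic rate
fluctuations, or slow non-stationarity — all present in real recordings.
Tests passing on synthetic data therefore validate the correction
machinery under the stated model, not robustness to those phenomena; the
matched-reference tooling (below) exists precisely to quantify how far a
real train departs from the non-bursty model.

## Spectral estimation and significance

Welch's method with non-overlapping 1024-sample Hamming-tapered segments
at Fs = 1 kHz: a one-sided 513-point density on the [0, 500] Hz grid with
resolution 1000/1024 ≈ 0.9766 Hz. Delta vectors are demeaned per segment
before tapering. The one-sided density normalisation makes the integral of
the spectrum approximate the series variance; every downstream statistic
is scale-invariant, so the convention only needs to be fixed, and is.

Candidate oscillations are sought in (0, 100] Hz (102 bins, labeled by
their exact grid frequency). Spike spectra approach the flat spectrum of a
matched-rate Poisson process at high frequencies, so the null level is
estimated from the same spectrum over [250, 500] Hz (both endpoints
included, 257 bins): a point is significant when it strictly exceeds
`hf_mean + z * hf_sd` with `z = Phi^-1(1 - alpha_c/102)` — `alpha_c` is the
family-wise level Bonferroni-split over the 102 search bins. Note the
one-sidedness: even `alpha_c = 1` leaves z ≈ 2.33, so points below the
high-frequency mean can never be flagged, and ROC curves need not reach
100% rates.

**Known limitation (small segment counts).** Welch PSD bins are scaled
chi-square variables; with ~30 segments their skew makes the Gaussian
quantile anticonservative. Measured on uncorrected 20 Hz Poisson trains of
30 segments, the family-wise positive rate at `alpha_c = 0.05` is ≈20%,
falling toward nominal as segments accumulate. This is an attribute of the
high-frequency CI construction itself, affecting both correction methods
identically; the residuals pipeline adds no false positives beyond that
baseline (asserted in the test suite) but inherits the inflation.

## ISI shuffling

*Unbroken trains*: the first spike stays anchored at its original time and
all ISIs are randomly permuted after it; spike count and the ISI multiset
are conserved exactly. (What to do with the pre-first/post-last dead
stretches is underdetermined; anchoring is the minimal-assumption choice.)
The control spectrum is the mean PSD over 100 surrogates (default), and
the corrected PSD is the pointwise ratio original/control; 0/0 bins map
to 1.

*Trial-windowed data*: ISIs from all rows are pooled, sorted longest
first, and greedily placed into randomly chosen rows with sufficient
remaining capacity; each row's ISIs are then re-sequenced and right-shifted
by a uniform random offset. The ISI multiset is conserved exactly; the
spike count may differ from the input by up to one spike per row that
gains or loses its leading spike. Longest-first packing makes placement
failure rare; a bounded number of fresh attempts precede an error.

## Recovery-period duration estimation

Outside the RP, firing is approximately Poisson, so the ISI density beyond
the RP is approximately exponential. The estimator fits
`PDF(x) = exp(B0 + B1*x)` to the ISI histogram cropped to `[L, max ISI]`
and renormalised, for `L = 1, 2, ...`, and scores each fit with the
deviance difference `dD(L) = D0 - D1` against the intercept-only model on
the same data. `dD` is low while the crop still contains RP bins and
peaks once the crop starts at the first post-RP lag; the first interior
local maximum `dD(L-1) < dD(L) > dD(L+1)` sets `n_r_hat = L* - 1`.
Equivalently (and verified as an invariant), assigning each `dD` a
chi-square(1) p-value and taking the first local minimum selects the same
lag. The minimum returnable estimate is 1 ms.

The GLM is Poisson with log link, so that `D0 - D1` equals −2 times the
log-likelihood ratio of the nested models. The family choice is load
bearing: with a Gaussian (least-squares) response, renormalising the
cropped histogram scales the deviance quadratically, which makes `dD`
grow monotonically in `L` on clean exponential tails and biases the first
local maximum late (empirically ~74% instead of ~87% exact recovery on
absolute-RP data). The fit is a damped 2-parameter IRLS with step-halving
(monotone deviance descent, slope-free fallback), verified against a
statsmodels Poisson GLM to ~1e-10.

Defaults: search up to `max_lag = 100` ms; require at least 50 ISIs.
Zero-count bins are retained in the fit (the log link constrains the
mean, not the data). Estimation is deterministic given the train.

## Bounded last-spike Poisson GLM

With `s*(t)` the time of the most recent spike strictly before bin `t`,

    log lambda(t) = beta_0 + sum_{j=1}^{n_r_hat} beta_j * [t - j == s*(t)]

predicts the per-ms spike intensity from the last-spike lag when that
spike is within the previous `n_r_hat` ms, and from the intercept alone
otherwise. Fitted rows are `t in [n_r_hat + 1, T]` only — the residual
series is defined exactly there, and fitting the same rows keeps the
score identities exact. The log-likelihood is concave, so the maximiser is
unique; because the lag indicators are mutually exclusive, the likelihood
separates over last-spike categories and the maximiser is available in
closed form (per-category empirical rates — the IRLS fixed point, which a
unit test confirms against statsmodels to machine precision). Standard
errors come from the analytic `(X'WX)^-1`.

Degenerate designs: a lag never followed by any spike (absolute RPs) has
an MLE of −infinity; its coefficient is reported floored at −20
(intensity ~1e-9 of baseline) with a flag, rather than diverging. A lag
with no occupied bins at all is dropped and reported. A train with no
spike beyond the bound leaves the intercept unidentified and errors.

Residuals are `r(t) = I(t) - lambda_hat(t)` for `t >= n_r_hat + 1`, with
the leading `n_r_hat` positions zero. Canonical-link score identities —
`sum r = 0` and `sum r * x_j = 0` per regressor, over the fitted rows —
hold to machine precision on every fit and are asserted in the suite.

For spectral analysis, the first 1024 ms segment consists of the first
`1024 - n_r_hat` residuals, demeaned, prepended with `n_r_hat` zeros
(preserving alignment and segment divisibility); subsequent segments are
the raw residual stream in 1024 ms blocks, demeaned per segment.

*Windowed variant*: the GLM pools category counts over all task windows
with the spike history reset at each window boundary (trials are
non-contiguous). Each window's residuals (length `W - n_r_hat`) are
demeaned and padded to 1024 ms — `n_r_hat` zeros in front (alignment, as
in the unbroken case) and the remainder behind (matching the uncorrected
windowed pipeline's trailing pad).

Under strong oscillation the lag-category rates absorb part of the
oscillatory variance (omitted-variable bias), so the residual spectrum
under-corrects rather than removes true peaks; the package reproduces
this behaviour, it does not attempt to fix it.

## Evaluation framework

Each corrected PSD is scored against the generating parameters: a **hit**
requires `m > 0` and at least one significant point among the 3 grid bins
nearest `f_osc` (ties toward the lower frequency; e.g. for 12 Hz the
eligible labels are 10.7422, 11.7188, 12.6953); a **false alarm** is any
significant point when `m = 0`, or, when `m > 0`, a significant point
outside the 10 bins nearest `f_osc` (equivalent to |f − f_osc| > 5 Hz on
this grid — the equivalence is asserted exhaustively in the suite).

The grid harness simulates every cell of a factorial parameter grid,
applies both corrections, and classifies each PSD over the 17-level
threshold grid {1, 5}×10^-8..-1 ∪ {1}. ROC analysis draws subsamples of
20 trains per `m > 0` cell (without replacement; trains failing either
method are excluded pairwise to keep the comparison paired), pools hit
and FA rates per threshold, crops all curves to the common FA interval
(max of minima to min of maxima, linear interpolation at the bounds),
and integrates each cropped curve by the trapezoidal rule. Method
differences are tested with a two-tailed paired t-test on the per-
subsample pAUC differences.

The primary grid crosses T ∈ {30, 60, 120}×1024 ms, f_osc ∈ {7, 9, 12,
20, 32} Hz, p_base = f_osc + {1, 2, 4, 8, 16, 32} Hz and m ∈ {0, 0.2, …,
1} at n_r = 9 ms, k = 0.7 — 540 cells. The full-scale study uses 100
trains per cell and 1000 subsamples; the desk-scale runs in this
repository use 3–10 trains per cell and 100 subsamples. Reported rates
are means over cells and subsamples, so reduced replication adds sampling
noise (~1 point SE at 4 reps/cell) but no bias; the problem sizes used
are printed by `scripts/acceptance.py` and stated in its header.

False-alarm descriptives: among corrected PSDs containing both hit- and
FA-classified points, the ratio of peak FA power to peak hit power and
the peak-FA frequency are averaged over PSDs, then cells (then
subsamples where applicable).

## Window and unit screening

For task-windowed recordings, per-window spike counts are screened for
firing-rate homogeneity: windows with fewer than 2 spikes are dropped;
the remaining counts are clustered by a 1-D Gaussian mixture with the
component count chosen by forward BIC search (stop when BIC rises or a
fit fails, keep the previous model); windows assigned to the largest
component are retained minus 3-sigma outliers of that component. The
mixture initialisation is a deterministic quantile partition (sorted
counts split into k contiguous blocks seeding means, variances and
weights), which emulates variance-partitioning initialisation and keeps
the search reproducible; k-means initialisation is available as an
option. Units are discarded when fewer than 30 windows survive or the
surviving-window mean rate is below 1 Hz (both configurable).

## Matched non-bursty reference simulations

Two named presets reproduce reference simulations matched to bursty
thalamic example units while containing no bursting component: `vla1`
(T = 118×1024 ms, f_osc = 13 Hz, p_base = 15 Hz) and `vla2` (T = 51×1024
ms, f_osc = 14 Hz, p_base = 21 Hz), both with m = 0.6, n_r = 1 ms, k = 0.
Against these, burstiness in real units shows up as an excess of 2–3 ms
ISIs and of consecutive 2–3 ms ISI pairs, and the detection rates of the
residuals pipeline on the presets bound what the method can do when its
1 ms estimated RP is actually the whole story.

## Numerical and reproducibility notes

* All randomness flows through `numpy.random.Generator`; grid runs derive
  one independent stream per (cell, rep) via `SeedSequence(seed,
  spawn_key=(cell, rep))`, so results are independent of iteration order
  and stable under parallel split.
* The simulator's per-ms Bernoulli loop is a numba kernel consuming a
  pre-drawn uniform array from the seeded generator.
* The 100-surrogate control spectra use a vectorised rfft periodogram
  identical to the scipy Welch path to ~1e-12 (asserted in the suite).
* Exceedance at exactly the CI threshold is non-significant (strict
  inequality); a constant spectrum flags nothing.
* Ratio spectra define 0/0 := 1; a zero control bin under nonzero
  original power is an error.
* pAUC integration treats curves as polylines ordered by threshold;
  vertical segments (tied FA values) contribute zero area.
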