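# spikespectra

Recovery-period-corrected power spectra for neuronal spike trains.

## The problem

Spectral analysis is the standard route to detecting oscillations in
neural activity, but applying it to single-unit spike trains runs into
the post-spike **recovery period** (RP) — refractoriness and longer
pauses that suppress spiking for the first `n_r` ms after each spike.
The RP distorts the spike-train power spectral density (PSD): a trough
over the low frequencies and elevated, ringing power at high
frequencies, growing with firing rate and RP duration. A significance
test that assumes a flat (Poisson) baseline then misses real oscillatory
peaks sunk in the trough and flags distortion-driven power elsewhere.

The package is aimed at systems neuroscientists analysing single-unit
recordings (e.g. basal-ganglia/thalamic units, where pathological
alpha-beta oscillations coexist with sparse firing), and implements two
corrections plus everything needed to compare them on ground-truth
synthetic data:

* **ISI-shuffling correction** (the established approach): estimate the
  spectrum of the matched renewal process by averaging Welch PSDs of
  ISI-permuted surrogate trains, and divide it out. Removes the RP — but
  also removes any rhythmicity carried by the inter-spike-interval
  distribution, which is exactly where the signal lives when a unit
  fires about once per oscillation cycle.
* **Point-process residuals correction**: estimate the RP duration
  `n_r_hat` from the ISI distribution, fit a *bounded last-spike*
  Poisson GLM

  `log lambda(t | H_t, beta) = beta_0 + sum_{j=1..n_r_hat} beta_j * delta_{t-j, s*(t)}`

  (where `s*(t)` is the time of the most recent spike, so the lag
  indicators model only the first `n_r_hat` ms of the post-spike
  hazard), and take the Welch PSD of the raw residuals
  `r(t) = I(t) - lambda_hat(t)`. Only RP-attributable variance is
  removed; longer-lag temporal structure survives into the corrected
  spectrum.

Also included: the inhomogeneous-Poisson spike-train simulator with
exponential recovery (`p_RP(t) = p_SS(t) * k^(n_r+1-n)`), the
high-frequency-derived one-sided CI significance test (family-wise
`alpha_c`, Bonferroni-split over the 102 search bins in (0, 100] Hz),
hit/false-alarm scoring, subsampled partial-ROC/pAUC comparison, and
GMM-based screening of task windows for firing-rate homogeneity.

## Worked example

A sparse oscillatory unit: 9 ms recovery period (k = 0.7), 9 Hz
sinusoidal drive at 60% modulation, ~10.5 Hz mean rate — i.e. roughly
one spike per oscillation cycle.

```python
import numpy as np
import spikespectra as ss

params = ss.SimParams(rate_hz=11.0, m=0.6, f_osc=9.0, n_r=9, k=0.7, T=60 * 1024)
train = ss.simulate_spike_train(params, rng=1)

model = ss.BoundedLastSpikeModel(train)   # estimates n_r_hat from the ISIs
res = model.fit()
print(res.summary())

psd = res.residual_psd()
sig = ss.significance_test(psd, alpha_c=0.05)
print("residuals:", np.round(sig.significant_freqs(), 2))

corrected, _ = ss.shuffling_corrected_psd(train, ss.ShuffleConfig(100, seed=1))
print("shuffling:", np.round(ss.significance_test(corrected, 0.05).significant_freqs(), 2))
```

Output:

```
Bounded last-spike point process model (Poisson GLM, log link)
  train length: 61440 ms, 646 spikes
  RP duration bound n_r_hat: 9 ms
  fitted rows: 59497   converged: True
  log-likelihood: -3554.4974
      term       coef  exp(coef)    std err
    beta_0    -4.4827   0.011302     0.0399
    beta_1   -20.0000   0.000000        nan  (floored: no spikes at this lag)
    beta_2    -1.2949   0.273922     0.7082
    ...
    beta_9    -0.1791   0.836003     0.4102
residuals: [8.79]
shuffling: []
```

Reading the output: the estimated RP duration matches the 9 ms ground
truth; `exp(beta_0) = 0.0113` recovers the ~11 Hz base rate per ms, and
the `exp(beta_j)` rise toward 1 across the RP, tracking the ground-truth
recovery profile `k^(n_r+1-j)` (lags with few events are noisy, and lags
never followed by a spike are reported floored rather than diverging to
−infinity). The residuals-corrected PSD flags the bin nearest 9 Hz
(8.79 Hz on the 0.9766 Hz grid) at family-wise `alpha_c = 0.05`, while
the shuffling correction — which removes the ISI-borne rhythmicity along
with the RP — misses the same oscillation on this train.

A command-line interface covers the same workflows
(`spikespectra simulate | correct | rp-estimate | evaluate | roc |
screen-windows`); see `spikespectra --help`.

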