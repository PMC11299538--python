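"""Bounded last-spike point-process model and the residuals-corrected PSD.

The model is a Poisson GLM (log link) on the binary 1 kHz spike indicator:

    log lambda(t) = beta_0 + sum_{j=1}^{n_r_hat} beta_j * [t - s*(t) == j]

where ``s*(t)`` is the time of the most recent spike strictly before bin
``t``. Exactly one lag indicator is active when the last spike fell within
the previous ``n_r_hat`` ms, and none otherwise, so the model captures the
recovery-period (RP) portion of the post-spike hazard and nothing else.
The raw residual series ``r(t) = I(t) - lambda_hat(t)`` (defined for
``t >= n_r_hat + 1``) carries the remaining temporal structure; its Welch
PSD is the "residuals-corrected" spectrum.

Because the lag indicators are mutually exclusive, the (concave) Poisson
log-likelihood separates over last-spike categories and its unique
maximiser is available in closed form: the fitted intensity for category
``c`` is the empirical spike rate ``k_c / n_c`` over the bins in that
category, which is exactly the point IRLS converges to. ``fit`` computes
this maximiser directly (unit tests verify agreement with an IRLS fit of
the same design). Lags never followed by a spike (absolute RPs) have
maximum-likelihood coefficients of -infinity; these are reported floored
at -20 (intensity ~ 0) rather than diverging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rp import RpEstimate, RpEstimationError, estimate_rp_duration
from .simulate import SpikeTrain, TrialMatrix
from .spectra import NFFT, Psd, welch_psd

__all__ = [
    "COEF_FLOOR",
    "BoundedLastSpikeModel",
    "BoundedLastSpikeResults",
    "build_design",
    "last_spike_lags",
    "residuals_corrected_psd",
    "residuals_corrected_psd_windowed",
]

#: Floor applied to coefficients whose MLE diverges to -infinity
#: (a lag never followed by a spike); exp(beta0 - 20) is numerically ~0.
COEF_FLOOR = -20.0


def last_spike_lags(delta: np.ndarray) -> np.ndarray:
    """Latency (ms) since the most recent spike strictly before each bin.

    ``lags[t] = t - s`` where ``s`` is the last spiking bin with ``s < t``;
    bins before the first spike get a sentinel larger than any real lag.
    """
    delta = np.asarray(delta)
    T = delta.shape[0]
    spike_idx = np.flatnonzero(delta)
    lags = np.full(T, T + 1, dtype=np.int64)
    if spike_idx.size:
        pos = np.searchsorted(spike_idx, np.arange(T), side="left") - 1
        has_prev = pos >= 0
        lags[has_prev] = np.arange(T)[has_prev] - spike_idx[pos[has_prev]]
    return lags


def build_design(train: SpikeTrain, n_r_hat: int):
    """Design for the bounded last-spike GLM.

    Returns ``(y, X, rows)``: the response over the fitted rows
    ``t in [n_r_hat + 1, T]`` (0-based index ``n_r_hat .. T-1``), the
    ``n_r_hat`` mutually exclusive lag-indicator columns, and the 0-based
    row indices into the original train. At most one indicator is active
    per row; all are 0 when the last spike is older than ``n_r_hat`` ms or
    absent.
    """
    if n_r_hat < 1:
        raise ValueError("n_r_hat must be >= 1")
    delta = train.delta
    lags = last_spike_lags(delta)
    rows = np.arange(n_r_hat, len(delta))
    row_lags = lags[rows]
    X = np.zeros((rows.size, n_r_hat), dtype=float)
    for j in range(1, n_r_hat + 1):
        X[:, j - 1] = row_lags == j
    y = delta[rows].astype(float)
    return y, X, rows


def _category_counts(row_lags: np.ndarray, y: np.ndarray, n_r_hat: int):
    """Per-category bin and spike counts.

    Category 0 collects the out-of-RP rows (last spike older than
    ``n_r_hat`` ms, or no spike yet); categories 1..n_r_hat collect the
    rows whose active lag indicator is j.
    """
    cat = np.where(row_lags <= n_r_hat, row_lags, 0).astype(np.int64)
    n_c = np.bincount(cat, minlength=n_r_hat + 1).astype(float)
    k_c = np.bincount(cat, weights=y, minlength=n_r_hat + 1)
    return n_c, k_c


def _fit_categories(n_c: np.ndarray, k_c: np.ndarray, n_r_hat: int) -> dict:
    """Exact Poisson-GLM MLE from last-spike category counts."""
    if k_c.sum() < 1:
        raise ValueError("no spikes in the fitted range")
    if n_c[0] == 0 or k_c[0] == 0:
        raise ValueError(
            "no out-of-RP spikes: the intercept is not identified "
            "(n_r_hat may be too large for this train)"
        )
    beta0 = float(np.log(k_c[0] / n_c[0]))
    params = np.full(n_r_hat + 1, np.nan)
    params[0] = beta0
    occupied = n_c[1:] > 0
    followed = k_c[1:] > 0
    active = occupied & followed
    floored = np.flatnonzero(occupied & ~followed) + 1
    dropped = np.flatnonzero(~occupied) + 1
    with np.errstate(divide="ignore"):
        params[1:][active] = np.log(k_c[1:][active] / n_c[1:][active]) - beta0
    params[floored] = COEF_FLOOR

    # Fitted intensity per category (floored categories use the cap).
    mu_c = np.empty(n_r_hat + 1)
    mu_c[0] = k_c[0] / n_c[0]
    with np.errstate(invalid="ignore"):
        mu_c[1:] = np.where(n_c[1:] > 0, k_c[1:] / np.maximum(n_c[1:], 1), np.nan)
    mu_c[floored] = np.exp(beta0 + COEF_FLOOR)

    # log L = sum_c [k_c log mu_c - n_c mu_c] (binary y, so log(y!) = 0).
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(k_c > 0, k_c * np.log(mu_c), 0.0) - n_c * np.nan_to_num(mu_c)
    llf = float(np.nansum(terms))

    # Asymptotic covariance (X'WX)^-1 over the identified columns.
    bse = np.full(n_r_hat + 1, np.nan)
    act_idx = np.flatnonzero(active) + 1
    dim = 1 + act_idx.size
    info = np.zeros((dim, dim))
    w0 = n_c[0] * mu_c[0]
    info[0, 0] = w0 + float((n_c[act_idx] * mu_c[act_idx]).sum())
    for i, j in enumerate(act_idx, start=1):
        w = n_c[j] * mu_c[j]
        info[0, i] = info[i, 0] = w
        info[i, i] = w
    cov = np.linalg.inv(info)
    bse[0] = np.sqrt(cov[0, 0])
    bse[act_idx] = np.sqrt(np.diag(cov)[1:])

    n_fitted = float(n_c[0] + n_c[act_idx].sum())
    return {
        "params": params, "bse": bse, "llf": llf,
        "floored_lags": floored, "dropped_lags": dropped,
        "n_fitted_rows": int(n_fitted),
    }


def _intensity_from_params(row_lags: np.ndarray, params: np.ndarray,
                           n_r_hat: int) -> np.ndarray:
    """Predicted per-ms intensity for each row given its last-spike lag."""
    eta = np.full(row_lags.size, params[0])
    in_rp = row_lags <= n_r_hat
    lag_vals = np.where(in_rp, row_lags, 1)
    eta += np.where(
        in_rp, np.nan_to_num(params[1:][lag_vals - 1], nan=COEF_FLOOR), 0.0
    )
    return np.exp(eta)


@dataclass
class BoundedLastSpikeResults:
    """Fit results: coefficients, uncertainties, diagnostics, residuals.

    ``params`` is ``[beta_0, beta_1, ..., beta_n_r_hat]``. ``bse`` entries
    are NaN for floored or dropped coefficients. ``resid`` is the raw
    residual series over the full train length with the leading
    ``n_r_hat`` positions zero.
    """

    model: "BoundedLastSpikeModel"
    params: np.ndarray
    bse: np.ndarray
    llf: float
    converged: bool
    n_fitted_rows: int
    floored_lags: np.ndarray
    dropped_lags: np.ndarray
    rp_estimate: RpEstimate | None = field(default=None, repr=False)

    @property
    def n_r_hat(self) -> int:
        return self.model.n_r_hat

    @property
    def beta0(self) -> float:
        return float(self.params[0])

    @property
    def beta(self) -> np.ndarray:
        """Lag coefficients beta_1..beta_n_r_hat."""
        return self.params[1:]

    @property
    def fittedvalues(self) -> np.ndarray:
        """Predicted intensity per ms over fitted bins (leading bins NaN)."""
        delta = self.model.train.delta
        lags = last_spike_lags(delta)
        mu = np.full(len(delta), np.nan)
        rows = np.arange(self.n_r_hat, len(delta))
        mu[rows] = _intensity_from_params(lags[rows], self.params, self.n_r_hat)
        return mu

    @property
    def resid(self) -> np.ndarray:
        """Raw residuals r(t) = I(t) - lambda_hat(t); leading n_r_hat zeros."""
        delta = self.model.train.delta.astype(float)
        r = delta - self.fittedvalues
        r[: self.n_r_hat] = 0.0
        return r

    def residual_psd(self) -> Psd:
        """Welch PSD of the residual series (see residuals_corrected_psd)."""
        return _residual_series_psd(self.resid, self.n_r_hat)

    def summary(self) -> str:
        lines = [
            "Bounded last-spike point process model (Poisson GLM, log link)",
            f"  train length: {len(self.model.train)} ms, "
            f"{self.model.train.n_spikes} spikes",
            f"  RP duration bound n_r_hat: {self.n_r_hat} ms",
            f"  fitted rows: {self.n_fitted_rows}   converged: {self.converged}",
            f"  log-likelihood: {self.llf:.4f}",
            f"  {'term':>8} {'coef':>10} {'exp(coef)':>10} {'std err':>10}",
            f"  {'beta_0':>8} {self.beta0:10.4f} {np.exp(self.beta0):10.6f} "
            f"{self.bse[0]:10.4f}",
        ]
        for j in range(1, self.n_r_hat + 1):
            b = self.params[j]
            note = ""
            if j in self.floored_lags:
                note = "  (floored: no spikes at this lag)"
            if j in self.dropped_lags:
                note = "  (dropped: lag never occupied)"
            coef = f"{b:10.4f}" if np.isfinite(b) else f"{'nan':>10}"
            ecoef = f"{np.exp(b):10.6f}" if np.isfinite(b) else f"{'nan':>10}"
            se = f"{self.bse[j]:10.4f}" if np.isfinite(self.bse[j]) else f"{'nan':>10}"
            lines.append(f"  {f'beta_{j}':>8} {coef} {ecoef} {se}{note}")
        return "\n".join(lines)


class BoundedLastSpikeModel:
    """Bounded last-spike Poisson GLM for a binary 1 kHz spike train.

    Parameters
    ----------
    train : SpikeTrain
        The delta vector to model.
    n_r_hat : int, optional
        RP duration bound in ms. When omitted it is estimated from the ISI
        distribution (:func:`~spikespectra.rp.estimate_rp_duration`).
    max_lag, min_isis :
        Passed to the RP estimator when ``n_r_hat`` is not supplied.
    """

    def __init__(self, train: SpikeTrain, n_r_hat: int | None = None,
                 max_lag: int = 100, min_isis: int = 50):
        self.train = train
        self.rp_estimate: RpEstimate | None = None
        if n_r_hat is None:
            self.rp_estimate = estimate_rp_duration(
                train, max_lag=max_lag, min_isis=min_isis
            )
            n_r_hat = self.rp_estimate.n_r_hat
        if n_r_hat < 1:
            raise ValueError("n_r_hat must be >= 1")
        self.n_r_hat = int(n_r_hat)

    @classmethod
    def from_times(cls, times_ms, T: int, **kwargs) -> "BoundedLastSpikeModel":
        return cls(SpikeTrain.from_times(times_ms, T), **kwargs)

    def fit(self) -> BoundedLastSpikeResults:
        """Maximum-likelihood fit (exact; see the module docstring)."""
        delta = self.train.delta
        rows = np.arange(self.n_r_hat, len(delta))
        row_lags = last_spike_lags(delta)[rows]
        y = delta[rows].astype(float)
        n_c, k_c = _category_counts(row_lags, y, self.n_r_hat)
        fit = _fit_categories(n_c, k_c, self.n_r_hat)
        return BoundedLastSpikeResults(
            model=self, converged=True, rp_estimate=self.rp_estimate, **fit
        )


def _residual_series_psd(r: np.ndarray, n_r_hat: int) -> Psd:
    """Assemble the Welch input from a residual series and estimate the PSD.

    The first segment holds the initial ``1024 - n_r_hat`` residuals,
    demeaned, prepended with ``n_r_hat`` zeros (keeping alignment with the
    original series and divisibility by 1024). Subsequent segments are the
    raw residual stream in 1024 ms blocks, demeaned segment-wise.
    """
    T = r.shape[0]
    if T % NFFT != 0:
        raise ValueError(f"residual series length must be a multiple of {NFFT}")
    out = np.array(r, dtype=float)
    first = out[n_r_hat:NFFT]
    out[n_r_hat:NFFT] = first - first.mean()
    out[:n_r_hat] = 0.0
    for s in range(1, T // NFFT):
        seg = out[s * NFFT:(s + 1) * NFFT]
        out[s * NFFT:(s + 1) * NFFT] = seg - seg.mean()
    return welch_psd(out, demean_per_segment=False)


def residuals_corrected_psd(
    train: SpikeTrain, n_r_hat: int | None = None,
    max_lag: int = 100, min_isis: int = 50,
):
    """Full residuals pipeline on an unbroken train.

    Estimates the RP duration (unless supplied), fits the bounded
    last-spike GLM, and returns ``(Psd, RpEstimate | None, results)``.
    """
    if len(train) % NFFT != 0:
        raise ValueError(f"train length must be a multiple of {NFFT}")
    model = BoundedLastSpikeModel(
        train, n_r_hat=n_r_hat, max_lag=max_lag, min_isis=min_isis
    )
    results = model.fit()
    return results.residual_psd(), model.rp_estimate, results


def residuals_corrected_psd_windowed(
    trials: TrialMatrix, n_r_hat: int | None = None,
    max_lag: int = 100, min_isis: int = 50,
):
    """Residuals pipeline for trial-windowed data (1000 ms rows).

    The GLM is fit pooled over all rows with the spike history reset at
    each row boundary (trials are non-contiguous); the first ``n_r_hat`` ms
    of each row are unfitted. Per-row residuals are demeaned, zero-padded
    to 1024 ms (``n_r_hat`` leading + trailing zeros to fill the segment),
    concatenated and Welch-analysed.

    Returns ``(Psd, RpEstimate | None, fit dict)``.
    """
    W = trials.window_ms
    pad_tail = NFFT - W
    if pad_tail < 0:
        raise ValueError(f"window length {W} exceeds the {NFFT} ms segment")
    if n_r_hat is None:
        pooled = _pooled_train(trials)
        rp = estimate_rp_duration(pooled, max_lag=max_lag, min_isis=min_isis)
        n_r_hat = rp.n_r_hat
    else:
        rp = None
    if n_r_hat >= W:
        raise ValueError("n_r_hat must be smaller than the window length")

    # Pooled category counts across rows; history resets per row.
    n_c = np.zeros(n_r_hat + 1)
    k_c = np.zeros(n_r_hat + 1)
    row_lags_all = []
    for i in range(trials.n_trials):
        delta = trials.dmat[i]
        row_lags = last_spike_lags(delta)[n_r_hat:]
        y = delta[n_r_hat:].astype(float)
        nc, kc = _category_counts(row_lags, y, n_r_hat)
        n_c += nc
        k_c += kc
        row_lags_all.append(row_lags)
    fit = _fit_categories(n_c, k_c, n_r_hat)
    params = fit["params"]

    segments = []
    for i in range(trials.n_trials):
        delta = trials.dmat[i].astype(float)
        mu = _intensity_from_params(row_lags_all[i], params, n_r_hat)
        r = delta[n_r_hat:] - mu
        r -= r.mean()
        segments.append(np.concatenate([np.zeros(n_r_hat), r, np.zeros(pad_tail)]))
    psd = welch_psd(np.concatenate(segments), demean_per_segment=False)
    return psd, rp, fit


def _pooled_train(trials: TrialMatrix) -> SpikeTrain:
    """Concatenate rows for ISI-based RP estimation.

    Cross-row ISIs are a small contamination (one spurious interval per row
    boundary at most); acceptable for duration estimation, which depends on
    the short-lag shape of the ISI distribution.
    """
    return SpikeTrain(trials.dmat.ravel())
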