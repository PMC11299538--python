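"""Recovery-period duration estimation from the ISI distribution.

The estimator exploits a renewal-theory observation: outside the recovery
period (RP), spiking is approximately Poisson, so the ISI probability
density beyond the RP should follow a decaying exponential. A series of
right-shifted exponential curves ``PDF(x) = exp(B0) * exp(B1 * x)`` is fit
to the ISI PDF cropped to start at lag ``L = 1, 2, ...``. Each fit is
scored by the deviance difference ``dD(L) = D0 - D1`` between the
constant-only and constant-plus-slope models on the same cropped data. The
first interior local maximum of ``dD`` marks the first post-RP lag ``L*``,
and the RP duration estimate is ``n_r_hat = L* - 1``.

Equivalently, one may assign each ``dD`` a chi-square(1) p-value and seek
the first local minimum of the p-values; both rules select the same lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .simulate import SpikeTrain

__all__ = [
    "IsiPdf",
    "RpEstimate",
    "RpEstimationError",
    "isi_list",
    "isi_pdf",
    "shifted_exponential_fit",
    "estimate_rp_duration",
]


class RpEstimationError(RuntimeError):
    """Raised when the RP duration cannot be estimated from a spike train."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass
class IsiPdf:
    """ISI histogram over integer ms lags [1, max ISI], plus a cropped PDF."""

    lags: np.ndarray
    counts: np.ndarray

    def cropped_pdf(self, L: int):
        """Histogram values over [L, max ISI], renormalized to unit area."""
        if L < 1 or L > self.lags[-1]:
            raise ValueError(f"crop lag L={L} outside [1, {self.lags[-1]}]")
        values = self.counts[L - 1:].astype(float)
        total = values.sum()
        if total == 0:
            raise ValueError(f"no ISI mass at lags >= {L}")
        return self.lags[L - 1:], values / total


def isi_list(train: SpikeTrain) -> np.ndarray:
    """Successive spike-time differences in integer ms (needs >= 2 spikes)."""
    return train.isis()


def isi_pdf(train: SpikeTrain) -> IsiPdf:
    isis = isi_list(train)
    max_isi = int(isis.max())
    counts = np.bincount(isis, minlength=max_isi + 1)[1:]
    return IsiPdf(lags=np.arange(1, max_isi + 1), counts=counts)


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    # 2 * sum[y log(y/mu) - (y - mu)], with 0 log 0 = 0.
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu)
    return float(2.0 * terms.sum())


def shifted_exponential_fit(x, y):
    """Poisson GLM (log link) fit of ``y ~ exp(B0 + B1 * x)`` on PDF values.

    Returns ``(B0, B1, D1, D0)`` where ``D1`` is the deviance of the
    constant+slope model and ``D0`` that of the constant-only model (whose
    MLE is ``exp(B0) = mean(y)``) on the same data. With unit scale the
    deviance difference equals -2 times the log-likelihood ratio of the
    nested models, so ``dD = D0 - D1 >= 0`` always.

    The solver is a damped IRLS on the two coefficients (the regressor is
    centred internally for conditioning); step-halving enforces monotone
    deviance descent, and the slope-free solution is the fallback, so the
    returned ``D1`` never exceeds ``D0``. Zero-probability bins are
    retained (the log link constrains the mean, not the data).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 support points for the fit")
    if np.all(y <= 0):
        raise ValueError("PDF values have no mass")
    if np.count_nonzero(y) == 1:
        raise ValueError("degenerate support: all mass in one bin")
    x0 = x.mean()
    X = np.column_stack([np.ones_like(x), x - x0])
    ybar = float(y.mean())
    d0 = _poisson_deviance(y, np.full_like(y, ybar))

    b = np.array([np.log(ybar), 0.0])
    dev = d0
    for _ in range(100):
        eta = X @ b
        mu = np.exp(np.clip(eta, -500.0, 50.0))
        z = eta + (y - mu) / mu
        A = X.T @ (mu[:, None] * X)
        try:
            b_new = np.linalg.solve(A, X.T @ (mu * z))
        except np.linalg.LinAlgError:
            break
        step = b_new - b
        # Step-halving: accept only deviance-decreasing updates.
        for _ in range(30):
            cand = b + step
            mu_c = np.exp(np.clip(X @ cand, -500.0, 50.0))
            dev_c = _poisson_deviance(y, mu_c)
            if dev_c <= dev + 1e-12:
                break
            step = step / 2.0
        else:
            cand, dev_c = b, dev
        if np.max(np.abs(cand - b)) < 1e-10:
            b, dev = cand, dev_c
            break
        b, dev = cand, dev_c
    d1 = min(dev, d0)
    b0 = float(b[0] - b[1] * x0)
    return b0, float(b[1]), d1, d0


@dataclass
class RpEstimate:
    """RP duration estimate and the per-lag deviance-difference trace.

    ``trace`` rows are ``(L, B0, B1, D0, D1, dD, p_chi2)`` for each crop lag
    that was fit before the stopping rule fired.
    """

    n_r_hat: int
    trace: np.ndarray
    max_lag_searched: int

    @property
    def delta_d(self) -> np.ndarray:
        return self.trace[:, 5]

    @property
    def p_values(self) -> np.ndarray:
        return self.trace[:, 6]


def estimate_rp_duration(
    train: SpikeTrain, max_lag: int = 100, min_isis: int = 50
) -> RpEstimate:
    """Estimate the RP duration from a spike train (deterministic).

    Iterates crop lags ``L = 1, 2, ...`` and stops at the first interior
    local maximum ``dD(L-1) < dD(L) > dD(L+1)``; returns
    ``n_r_hat = L* - 1`` (so the minimum returnable estimate is 1 ms).
    Raises :class:`RpEstimationError` (with the trace attached) if no local
    maximum appears before ``max_lag`` or the train has too few ISIs.
    """
    try:
        isis = isi_list(train)
    except ValueError as exc:
        raise RpEstimationError(str(exc)) from exc
    if isis.size < min_isis:
        raise RpEstimationError(
            f"too few ISIs for stable RP estimation ({isis.size} < {min_isis})"
        )
    pdf = isi_pdf(train)
    limit = min(max_lag, int(pdf.lags[-1]) - 2)
    records = []
    for L in range(1, limit + 1):
        x, y = pdf.cropped_pdf(L)
        try:
            b0, b1, d1, d0 = shifted_exponential_fit(x, y)
        except ValueError as exc:
            raise RpEstimationError(
                f"exponential fit failed at crop lag {L}: {exc}",
                trace=np.asarray(records),
            ) from exc
        dd = d0 - d1
        records.append((L, b0, b1, d0, d1, dd, chi2.sf(dd, df=1)))
        if L >= 3 and records[-3][5] < records[-2][5] > records[-1][5]:
            trace = np.asarray(records)
            return RpEstimate(
                n_r_hat=L - 2, trace=trace, max_lag_searched=L
            )
    raise RpEstimationError(
        f"no interior local maximum of dD found within {limit} lags",
        trace=np.asarray(records),
    )
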