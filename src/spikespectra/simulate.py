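"""Synthetic spike-train generation.

Spike trains are simulated as a discrete-time (1 kHz) approximation of an
inhomogeneous Poisson process with two ingredients:

* a steady-state per-bin spike probability
  ``p_SS(t) = p_base + p_osc * sin(2*pi*f_osc*t/1000)``, where
  ``p_osc = m * p_base`` and ``m`` is the modulation index, and
* an exponentially recovering "recovery period" (RP): for the first ``n_r``
  ms after a spike, the steady-state probability is multiplied by
  ``k**(n_r + 1 - n)`` where ``n`` is the latency (ms) since that spike.

Each 1 ms bin draws an independent Bernoulli with the resulting probability,
so at most one spike can occupy a bin (orderliness). The output is a binary
"delta vector" at 1 kHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "SEGMENT_MS",
    "SimParams",
    "SpikeTrain",
    "TrialMatrix",
    "simulate_spike_train",
    "simulate_trial_matrix",
    "simulate_bursty_reference",
    "REFERENCE_PRESETS",
]

#: Welch segment length in ms; unbroken simulation durations must be a
#: multiple of this.
SEGMENT_MS = 1024


def _as_generator(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class SimParams:
    """Parameters of the spike-train generator.

    Parameters
    ----------
    rate_hz : float
        Steady-state base firing rate in Hz. Stored internally as the
        per-bin probability ``p_base = rate_hz / 1000``.
    m : float
        Modulation index in [0, 1]; the oscillation amplitude is
        ``p_osc = m * p_base``.
    f_osc : float
        Oscillation frequency in Hz.
    n_r : int
        Recovery-period duration in ms (>= 0).
    k : float
        Recovery steepness in [0, 1). ``k = 0`` gives an absolute RP.
    T : int
        Duration in ms; must be a positive multiple of 1024 for unbroken
        trains (trial windows relax this; see ``simulate_trial_matrix``).
    """

    rate_hz: float
    m: float
    f_osc: float
    n_r: int
    k: float
    T: int
    seed: int | None = field(default=None, compare=False)

    def __post_init__(self):
        if not 0.0 <= self.m <= 1.0:
            raise ValueError(f"modulation index m={self.m} outside [0, 1]")
        if not 0.0 <= self.k < 1.0:
            raise ValueError(f"recovery steepness k={self.k} outside [0, 1)")
        if self.n_r < 0 or int(self.n_r) != self.n_r:
            raise ValueError(f"n_r must be a nonnegative integer, got {self.n_r}")
        if self.rate_hz < 0:
            raise ValueError("rate_hz must be nonnegative")
        if self.p_base + self.p_osc >= 0.5:
            raise ValueError(
                "p_base + p_osc must be well below 0.5 per 1 ms bin "
                f"(got {self.p_base + self.p_osc:.3f}); lower rate_hz or m"
            )
        if self.T <= 0:
            raise ValueError("T must be positive")

    @property
    def p_base(self) -> float:
        """Per-bin steady-state spike probability."""
        return self.rate_hz / 1000.0

    @property
    def p_osc(self) -> float:
        """Per-bin oscillation amplitude (derived from ``m``, never stored)."""
        return self.m * self.p_base

    def validate_unbroken(self):
        if self.T % SEGMENT_MS != 0:
            raise ValueError(
                f"unbroken duration T={self.T} must be a multiple of {SEGMENT_MS} ms"
            )


@dataclass
class SpikeTrain:
    """A binary 1 kHz delta vector: 1 marks a spike in that 1 ms bin."""

    delta: np.ndarray
    fs: float = 1000.0

    def __post_init__(self):
        self.delta = np.ascontiguousarray(self.delta, dtype=np.uint8)
        if self.delta.ndim != 1:
            raise ValueError("delta vector must be one-dimensional")
        if np.any(self.delta > 1):
            raise ValueError("delta vector entries must be in {0, 1}")

    def __len__(self) -> int:
        return self.delta.shape[0]

    @property
    def n_spikes(self) -> int:
        return int(self.delta.sum())

    def spike_times(self) -> np.ndarray:
        """Spike times in integer ms (1-based, matching the ms-bin label)."""
        return np.flatnonzero(self.delta) + 1

    def isis(self) -> np.ndarray:
        """Inter-spike intervals in ms. Requires >= 2 spikes."""
        times = self.spike_times()
        if times.size < 2:
            raise ValueError("at least 2 spikes are required to form ISIs")
        return np.diff(times)

    @classmethod
    def from_times(cls, times_ms, T: int) -> "SpikeTrain":
        """Build a delta vector from 1-based integer spike times."""
        times = np.asarray(times_ms, dtype=np.int64)
        if times.size and (times.min() < 1 or times.max() > T):
            raise ValueError("spike times must lie in [1, T]")
        delta = np.zeros(T, dtype=np.uint8)
        delta[times - 1] = 1
        return cls(delta)


@dataclass
class TrialMatrix:
    """``n_trials x W`` binary matrix of fixed-length trial windows."""

    dmat: np.ndarray

    def __post_init__(self):
        self.dmat = np.ascontiguousarray(self.dmat, dtype=np.uint8)
        if self.dmat.ndim != 2:
            raise ValueError("trial matrix must be two-dimensional")
        if self.dmat.size and np.any(self.dmat > 1):
            raise ValueError("trial matrix entries must be in {0, 1}")

    @property
    def n_trials(self) -> int:
        return self.dmat.shape[0]

    @property
    def window_ms(self) -> int:
        return self.dmat.shape[1]

    def row(self, i: int) -> SpikeTrain:
        return SpikeTrain(self.dmat[i])


@njit(cache=True)
def _simulate_kernel(u, p_base, p_osc, f_osc, n_r, k):  # pragma: no cover
    T = u.shape[0]
    delta = np.zeros(T, dtype=np.uint8)
    two_pi = 2.0 * np.pi
    # Latency counter: a spike in bin t gives n = 1 at bin t + 1. Before any
    # first spike the unit is treated as outside the RP (steady state).
    last = -(n_r + 2)
    for i in range(T):
        t_ms = i + 1  # 1-based ms bin label
        p = p_base + p_osc * np.sin(two_pi * f_osc * t_ms * 0.001)
        n = i - last
        if n <= n_r:
            p = p * k ** (n_r + 1 - n)
        if u[i] < p:
            delta[i] = 1
            last = i
    return delta


def simulate_spike_train(params: SimParams, rng=None) -> SpikeTrain:
    """Draw one spike train from the inhomogeneous-Poisson RP process.

    ``rng`` may be a ``numpy.random.Generator`` or a seed; if omitted,
    ``params.seed`` is used. The same seed always yields the same train.
    """
    params.validate_unbroken()
    return _simulate_any_length(params, params.T, rng)


def _simulate_any_length(params: SimParams, T: int, rng=None) -> SpikeTrain:
    if rng is None:
        rng = params.seed
    gen = _as_generator(rng)
    u = gen.random(T)
    delta = _simulate_kernel(
        u, params.p_base, params.p_osc, float(params.f_osc), int(params.n_r),
        float(params.k),
    )
    return SpikeTrain(delta)


def simulate_trial_matrix(
    params: SimParams, n_trials: int, window_ms: int = 1000, rng=None
) -> TrialMatrix:
    """Simulate ``n_trials`` independent windows of ``window_ms`` ms each.

    Each row is an independent draw from the same process (no spike history
    crosses rows), emulating non-contiguous task windows.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be nonnegative")
    gen = _as_generator(rng if rng is not None else params.seed)
    rows = np.zeros((n_trials, window_ms), dtype=np.uint8)
    for i in range(n_trials):
        rows[i] = _simulate_any_length(params, window_ms, gen).delta
    return TrialMatrix(rows)


#: Matched non-bursty reference configurations (no bursting component,
#: parameters matched to the two empirical VLa example units).
REFERENCE_PRESETS: dict[str, SimParams] = {
    "vla1": SimParams(rate_hz=15.0, m=0.6, f_osc=13.0, n_r=1, k=0.0, T=118 * 1024),
    "vla2": SimParams(rate_hz=21.0, m=0.6, f_osc=14.0, n_r=1, k=0.0, T=51 * 1024),
}


def simulate_bursty_reference(preset: str, rng=None) -> SpikeTrain:
    """Simulate one train from a named matched-reference preset.

    These presets reproduce the "no bursting component" reference
    simulations used for comparison with burst-firing thalamic units.
    """
    try:
        params = REFERENCE_PRESETS[preset]
    except KeyError:
        raise KeyError(
            f"unknown preset {preset!r}; available: {sorted(REFERENCE_PRESETS)}"
        ) from None
    return simulate_spike_train(params, rng)
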