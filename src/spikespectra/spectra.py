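"""Welch power spectral density estimation and the high-frequency CI test.

All spectra live on a fixed 513-point one-sided grid spanning [0, 500] Hz
(Fs = 1 kHz, NFFT = 1024, frequency resolution 1000/1024 ~= 0.9766 Hz).
Frequency bins are labeled by their exact grid frequency (lower bound).

Significance of candidate oscillatory power in (0, 100] Hz (102 bins) is
assessed against a one-sided confidence bound built from the mean and SD of
the same spectrum over [250, 500] Hz, where spike spectra approach the flat
spectrum of a rate-matched Poisson process. The family-wise level alpha_c
is Bonferroni-split over the 102 search bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.stats import norm

__all__ = [
    "NFFT",
    "FS",
    "N_FREQS",
    "GRID_FREQS",
    "SEARCH_BINS",
    "HF_BINS",
    "Psd",
    "SignificanceResult",
    "welch_psd",
    "welch_psd_windowed",
    "significance_test",
    "significance_masks",
    "corrected_ratio",
]

NFFT = 1024
FS = 1000.0
N_FREQS = NFFT // 2 + 1  # 513
#: Exact grid frequencies: i * 1000/1024 for i = 0..512.
GRID_FREQS = np.arange(N_FREQS) * (FS / NFFT)
#: Indices of the (0, 100] Hz search range (102 bins).
SEARCH_BINS = np.flatnonzero((GRID_FREQS > 0) & (GRID_FREQS <= 100))
#: Indices of the [250, 500] Hz high-frequency reference range.
HF_BINS = np.flatnonzero((GRID_FREQS >= 250) & (GRID_FREQS <= 500))


@dataclass
class Psd:
    """One-sided power spectral density on the standard 513-point grid."""

    freqs: np.ndarray
    power: np.ndarray
    n_segments: int

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != (N_FREQS,) or self.power.shape != (N_FREQS,):
            raise ValueError(f"PSD must have exactly {N_FREQS} points")
        if np.any(self.power < 0):
            raise ValueError("PSD power must be nonnegative")

    def plot(self, ax=None, fmax: float = 100.0, **kwargs):
        """Plot the spectrum up to ``fmax`` Hz (lazy matplotlib import)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sel = self.freqs <= fmax
        ax.plot(self.freqs[sel], self.power[sel], **kwargs)
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("power")
        return ax


@dataclass
class SignificanceResult:
    """Outcome of the high-frequency-derived one-sided CI test.

    ``sig`` is a boolean vector over the 102 search bins in (0, 100] Hz;
    ``search_freqs`` carries the matching bin labels.
    """

    alpha_c: float
    threshold: float
    sig: np.ndarray
    hf_mean: float
    hf_sd: float

    @property
    def search_freqs(self) -> np.ndarray:
        return GRID_FREQS[SEARCH_BINS]

    @property
    def any_significant(self) -> bool:
        return bool(self.sig.any())

    def significant_freqs(self) -> np.ndarray:
        return self.search_freqs[self.sig]


def _segment_view(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("input must be a one-dimensional series")
    if x.size == 0 or x.size % NFFT != 0:
        raise ValueError(f"series length must be a positive multiple of {NFFT}")
    return x.reshape(-1, NFFT)


def welch_psd(x, demean_per_segment: bool = True) -> Psd:
    """Welch PSD: nonoverlapping 1024-sample Hamming-tapered segments.

    With ``demean_per_segment`` each segment has its own mean removed before
    tapering (matching the convention of demeaning the delta vectors
    segment-wise before calling the spectral estimator). One-sided density
    scaling: the integral of the spectrum approximates the series variance.
    """
    segs = _segment_view(x)
    freqs, power = signal.welch(
        segs,
        fs=FS,
        window="hamming",
        nperseg=NFFT,
        noverlap=0,
        nfft=NFFT,
        detrend="constant" if demean_per_segment else False,
        scaling="density",
        return_onesided=True,
        axis=-1,
    )
    return Psd(freqs=freqs, power=power.mean(axis=0), n_segments=segs.shape[0])


def welch_psd_windowed(trials, pad_ms: int = 24) -> Psd:
    """Welch PSD for trial-windowed data.

    Each row (one task window) is demeaned, zero-padded at the end by
    ``pad_ms`` to reach the 1024 ms segment size, and the rows are
    concatenated; the Welch stage then runs with per-segment demeaning
    disabled so the padding is preserved.
    """
    dmat = np.asarray(getattr(trials, "dmat", trials), dtype=float)
    if dmat.ndim != 2:
        raise ValueError("trials must be a 2-D trial matrix")
    if dmat.shape[1] + pad_ms != NFFT:
        raise ValueError(
            f"row length {dmat.shape[1]} + pad {pad_ms} must equal {NFFT}"
        )
    demeaned = dmat - dmat.mean(axis=1, keepdims=True)
    padded = np.concatenate(
        [demeaned, np.zeros((dmat.shape[0], pad_ms))], axis=1
    )
    return welch_psd(padded.ravel(), demean_per_segment=False)


def significance_test(psd: Psd, alpha_c: float = 0.05) -> SignificanceResult:
    """One-sided CI test over the (0, 100] Hz search range.

    The threshold is ``hf_mean + z * hf_sd`` with
    ``z = Phi^-1(1 - alpha_c / 102)``: ``alpha_c`` is the family-wise level,
    Bonferroni-split over the 102 search bins. Exceedance is strict, so with
    a constant spectrum (hf_sd = 0) nothing is flagged.
    """
    if not 0 < alpha_c <= 1:
        raise ValueError("alpha_c must lie in (0, 1]")
    hf = psd.power[HF_BINS]
    if hf.size < 2:
        raise ValueError("high-frequency reference range has too few bins")
    hf_mean = float(hf.mean())
    hf_sd = float(hf.std(ddof=1))
    z = norm.ppf(1.0 - alpha_c / SEARCH_BINS.size)
    threshold = hf_mean + z * hf_sd
    sig = psd.power[SEARCH_BINS] > threshold
    return SignificanceResult(
        alpha_c=alpha_c, threshold=threshold, sig=sig,
        hf_mean=hf_mean, hf_sd=hf_sd,
    )


def significance_masks(psd: Psd, alphas) -> np.ndarray:
    """Vectorized ``significance_test`` over several alpha levels.

    Returns a boolean array of shape ``(len(alphas), 102)``. Used by the
    evaluation harness when sweeping the ROC threshold grid.
    """
    alphas = np.asarray(alphas, dtype=float)
    hf = psd.power[HF_BINS]
    hf_mean = hf.mean()
    hf_sd = hf.std(ddof=1)
    z = norm.ppf(1.0 - alphas / SEARCH_BINS.size)
    thresholds = hf_mean + z * hf_sd
    return psd.power[SEARCH_BINS][None, :] > thresholds[:, None]


def corrected_ratio(psd_orig: Psd, psd_control: Psd) -> Psd:
    """Pointwise ratio of an original PSD to a control (null) PSD.

    Zero-over-zero bins are set to 1 by convention (both spectra agree that
    no power is present). A zero control under nonzero original power is an
    error: the correction is undefined there.
    """
    if not np.array_equal(psd_orig.freqs, psd_control.freqs):
        raise ValueError("PSDs must share the same frequency grid")
    orig = psd_orig.power
    ctrl = psd_control.power
    bad = (ctrl == 0) & (orig != 0)
    if np.any(bad):
        raise ValueError(
            "control PSD is zero where the original has power "
            f"(first offending bin: {psd_orig.freqs[bad][0]:.4f} Hz)"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where((ctrl == 0) & (orig == 0), 1.0, orig / np.where(ctrl == 0, 1.0, ctrl))
    return Psd(freqs=psd_orig.freqs, power=ratio, n_segments=psd_orig.n_segments)
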