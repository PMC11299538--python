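"""Firing-rate homogeneity screening of trial windows.

Real task-windowed recordings often show blocks of trials during which a
unit is silent or sparse, surrounded by blocks of regular spiking — a
symptom of non-stationarity that would corrupt spectral estimates. The
screen clusters per-window spike counts with a Gaussian mixture model,
using a BIC forward search over the number of components, keeps only the
windows assigned to the largest cluster, and drops 3-sigma outliers of
that cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

__all__ = ["WindowScreenResult", "UnitScreenResult", "select_windows", "screen_unit"]


@dataclass
class WindowScreenResult:
    """Outcome of the GMM window screen (indices refer to the input vector)."""

    kept: np.ndarray
    k_selected: int
    cluster_means: np.ndarray
    cluster_sds: np.ndarray
    cluster_weights: np.ndarray
    dropped_low: np.ndarray
    dropped_outlier: np.ndarray
    bic_trace: np.ndarray


def _quantile_partition_init(x: np.ndarray, k: int):
    """Deterministic initial GMM parameters from k contiguous sorted blocks.

    Emulates variance-partitioning initialisation: the sorted counts are
    split into k equal blocks whose means/variances/proportions seed the
    mixture, keeping the forward search reproducible.
    """
    xs = np.sort(x)
    blocks = np.array_split(xs, k)
    means = np.array([[b.mean()] for b in blocks])
    variances = np.array([max(b.var(), 1e-6) for b in blocks])
    weights = np.array([len(b) / len(xs) for b in blocks])
    return means, variances, weights


def select_windows(
    spike_counts, rng=None, init: str = "quantile", max_k: int | None = None
) -> WindowScreenResult:
    """Screen trial windows for firing-rate homogeneity.

    Steps: drop windows with < 2 spikes; fit GMMs with k = 1, 2, ... until
    the BIC rises or a fit fails, keeping k-1; hard-assign windows; retain
    the largest cluster; drop windows more than 3 cluster SDs from its
    mean. ``init`` is "quantile" (deterministic, default) or "kmeans".
    """
    counts = np.asarray(spike_counts, dtype=float)
    if counts.ndim != 1:
        raise ValueError("spike_counts must be a 1-D vector")
    eligible = np.flatnonzero(counts >= 2)
    dropped_low = np.flatnonzero(counts < 2)
    if eligible.size == 0:
        raise ValueError("all windows have < 2 spikes")
    x = counts[eligible][:, None]
    seed = None
    if rng is not None:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        seed = int(gen.integers(0, 2**31 - 1))

    import warnings

    best = None
    bics = []
    limit = max_k if max_k is not None else x.shape[0]
    for k in range(1, limit + 1):
        kwargs: dict = {"n_components": k, "covariance_type": "diag",
                        "random_state": seed}
        if init == "quantile":
            means, variances, weights = _quantile_partition_init(x[:, 0], k)
            kwargs |= {
                "means_init": means,
                "precisions_init": (1.0 / variances)[:, None],
                "weights_init": weights,
                "n_init": 1,
            }
        elif init != "kmeans":
            raise ValueError(f"unknown init {init!r}")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                gmm = GaussianMixture(**kwargs).fit(x)
            bic = gmm.bic(x)
        except Exception:
            break  # convergence failure counts as the stopping condition
        if bics and bic > bics[-1]:
            bics.append(bic)
            break
        bics.append(bic)
        best = gmm
    if best is None:
        raise ValueError("no GMM could be fit to the spike counts")

    labels = best.predict(x)
    counts_per = np.bincount(labels, minlength=best.n_components)
    g = int(np.argmax(counts_per))
    mu_g = float(best.means_[g, 0])
    sd_g = float(np.sqrt(best.covariances_[g, 0]))
    in_g = labels == g
    outlier = in_g & (np.abs(x[:, 0] - mu_g) > 3 * sd_g)
    kept_mask = in_g & ~outlier
    return WindowScreenResult(
        kept=eligible[kept_mask],
        k_selected=best.n_components,
        cluster_means=best.means_[:, 0],
        cluster_sds=np.sqrt(best.covariances_[:, 0]),
        cluster_weights=best.weights_,
        dropped_low=dropped_low,
        dropped_outlier=eligible[outlier],
        bic_trace=np.asarray(bics),
    )


@dataclass
class UnitScreenResult:
    keep: bool
    reasons: tuple


def screen_unit(
    n_windows: int, mean_fr_hz: float,
    min_windows: int = 30, min_fr_hz: float = 1.0,
) -> UnitScreenResult:
    """Unit-level screen: enough surviving windows and a minimum mean rate."""
    reasons = []
    if n_windows < min_windows:
        reasons.append(f"only {n_windows} surviving windows (< {min_windows})")
    if mean_fr_hz < min_fr_hz:
        reasons.append(f"mean FR {mean_fr_hz:.2f} Hz (< {min_fr_hz} Hz)")
    return UnitScreenResult(keep=not reasons, reasons=tuple(reasons))
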