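"""Hit/false-alarm labeling, grid simulation harness, and pROC comparison.

A corrected PSD is scored against the ground-truth oscillation frequency
``f_osc`` of the simulation that produced it:

* hit  — the train was oscillatory (``m > 0``) and at least one of the 3
  grid bins nearest ``f_osc`` is significant;
* false alarm — any significant bin when ``m = 0``, or (``m > 0``) a
  significant bin outside the 10 bins nearest ``f_osc`` (equivalently,
  more than ~5 Hz away).

The harness simulates a parameter grid, applies both correction methods,
classifies every PSD over a grid of family-wise alpha levels, and compares
the methods through subsampled partial ROC curves (pAUC with a paired
t-test).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ttest_rel

from . import ppm, shuffling
from .rp import RpEstimationError, estimate_rp_duration
from .simulate import SEGMENT_MS, SimParams, simulate_spike_train
from .spectra import GRID_FREQS, SEARCH_BINS, Psd, significance_masks, significance_test

__all__ = [
    "ALPHA_GRID",
    "DetectionLabel",
    "GridSpec",
    "hit_bins",
    "fa_exempt_bins",
    "classify_psd",
    "classify_masks",
    "run_grid",
    "subsample_roc",
    "pauc_compare",
    "fa_descriptives",
    "primary_grid",
    "absolute_rp_grid",
    "rp_estimates_for_grid",
    "rp_accuracy",
    "mean_rates_at_alpha",
    "matched_reference_rates",
    "matched_reference_isi_stats",
]

logger = logging.getLogger(__name__)

#: ROC threshold grid: {1, 5} x 10^{-8..-1}, plus 1 (17 sorted levels).
ALPHA_GRID = np.sort(
    np.concatenate([np.outer([1.0, 5.0], 10.0 ** np.arange(-8, 0)).ravel(), [1.0]])
)


@dataclass(frozen=True)
class DetectionLabel:
    """Binary per-PSD labels: contains >= 1 hit / >= 1 false alarm."""

    hit: bool
    fa: bool


def _nearest_bins(f_osc: float, n: int) -> np.ndarray:
    """Indices (into the 102 search bins) of the n bins nearest ``f_osc``.

    Distance ties are broken toward the lower frequency.
    """
    freqs = GRID_FREQS[SEARCH_BINS]
    dist = np.abs(freqs - f_osc)
    order = np.lexsort((freqs, dist))
    return np.sort(order[:n])


def hit_bins(f_osc: float) -> np.ndarray:
    """Search-bin indices eligible to count as a hit (3 nearest bins)."""
    return _nearest_bins(f_osc, 3)


def fa_exempt_bins(f_osc: float) -> np.ndarray:
    """Search-bin indices exempt from FA counting (10 nearest bins)."""
    return _nearest_bins(f_osc, 10)


def classify_psd(sig, f_osc: float | None, m: float) -> DetectionLabel:
    """Label one significance result as hit / false alarm.

    ``sig`` is a :class:`~spikespectra.spectra.SignificanceResult` or a
    boolean vector over the 102 search bins.
    """
    mask = np.asarray(getattr(sig, "sig", sig), dtype=bool)
    if mask.shape != (SEARCH_BINS.size,):
        raise ValueError("significance mask must cover the 102 search bins")
    if m > 0:
        if f_osc is None or not 0 < f_osc <= 100:
            raise ValueError("f_osc must lie in (0, 100] Hz when m > 0")
        hit = bool(mask[hit_bins(f_osc)].any())
        fa_mask = mask.copy()
        fa_mask[fa_exempt_bins(f_osc)] = False
        fa = bool(fa_mask.any())
    else:
        hit = False
        fa = bool(mask.any())
    return DetectionLabel(hit=hit, fa=fa)


def classify_masks(psd: Psd, f_osc: float | None, m: float, alphas) -> np.ndarray:
    """Hit/FA labels over several alpha levels at once.

    Returns an integer array of shape ``(len(alphas), 2)`` with columns
    (hit, fa).
    """
    masks = significance_masks(psd, alphas)
    out = np.zeros((masks.shape[0], 2), dtype=np.int8)
    if m > 0:
        hb = hit_bins(f_osc)
        ex = fa_exempt_bins(f_osc)
        out[:, 0] = masks[:, hb].any(axis=1)
        fa_masks = masks.copy()
        fa_masks[:, ex] = False
        out[:, 1] = fa_masks.any(axis=1)
    else:
        out[:, 1] = masks.any(axis=1)
    return out


@dataclass(frozen=True)
class GridSpec:
    """A factorial simulation grid.

    ``T_segments`` are durations in 1024 ms segments. ``p_base_offsets``
    sets the base rate as ``f_osc + offset`` (Hz) unless ``p_base_values``
    is given, in which case base rates are taken directly and offsets are
    ignored.
    """

    T_segments: tuple = (30, 60, 120)
    f_osc_values: tuple = (7.0, 9.0, 12.0, 20.0, 32.0)
    p_base_offsets: tuple = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
    m_values: tuple = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    n_r: int = 9
    k: float = 0.7
    reps: int = 100
    p_base_values: tuple | None = None

    def cells(self):
        """Yield (cell_index, SimParams-without-seed) over the full crossing."""
        idx = 0
        for T_seg in self.T_segments:
            for f_osc in self.f_osc_values:
                rates = (
                    self.p_base_values
                    if self.p_base_values is not None
                    else tuple(f_osc + off for off in self.p_base_offsets)
                )
                for rate in rates:
                    for m in self.m_values:
                        yield idx, SimParams(
                            rate_hz=rate, m=m, f_osc=f_osc,
                            n_r=self.n_r, k=self.k, T=T_seg * SEGMENT_MS,
                        )
                        idx += 1

    @property
    def n_cells(self) -> int:
        return sum(1 for _ in self.cells())


def primary_grid(reps: int = 100) -> GridSpec:
    """The primary 540-cell synthetic grid (relative RP: n_r=9, k=0.7)."""
    return GridSpec(reps=reps)


def absolute_rp_grid(reps: int = 100) -> GridSpec:
    """The altered-RP variant: 3 ms absolute RP (n_r=3, k=0)."""
    return GridSpec(n_r=3, k=0.0, reps=reps)


def run_grid(
    grid: GridSpec,
    seed: int = 0,
    alphas=ALPHA_GRID,
    methods: tuple = ("residuals", "shuffling"),
    n_surrogates: int = 100,
    collect_psds: bool = False,
    progress: bool = False,
) -> pd.DataFrame:
    """Simulate a grid and classify both methods' corrected PSDs.

    Returns a tidy frame with one row per train x method x alpha:
    columns ``cell, T_seg, f_osc, p_base, m, rep, n_r_hat, method, alpha,
    hit, fa`` (hit/fa are NaN where a method failed on a train; failures
    are logged, never fatal). With ``collect_psds`` the corrected power
    vectors are attached as ``df.attrs["psds"]`` keyed by
    ``(cell, rep, method)``.

    Per-train RNG streams are derived from ``seed`` and the (cell, rep)
    index so results are independent of iteration order.
    """
    alphas = np.asarray(alphas, dtype=float)
    rows = []
    psds: dict = {}
    for cell, params in grid.cells():
        for rep in range(grid.reps):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(cell, rep))
            rng = np.random.default_rng(ss)
            train = simulate_spike_train(params, rng)
            base = dict(
                cell=cell, T_seg=params.T // SEGMENT_MS, f_osc=params.f_osc,
                p_base=params.rate_hz, m=params.m, rep=rep,
            )
            n_r_hat = np.nan
            method_psds = {}
            try:
                rp = estimate_rp_duration(train)
                n_r_hat = rp.n_r_hat
            except RpEstimationError as exc:
                logger.warning("RP estimation failed (cell %s rep %s): %s",
                               cell, rep, exc)
                rp = None
            if "residuals" in methods:
                if rp is not None:
                    try:
                        psd, _, _ = ppm.residuals_corrected_psd(
                            train, n_r_hat=rp.n_r_hat
                        )
                        method_psds["residuals"] = psd
                    except Exception as exc:
                        logger.warning("residuals failed (cell %s rep %s): %s",
                                       cell, rep, exc)
            if "shuffling" in methods:
                try:
                    corrected, _ = shuffling.shuffling_corrected_psd(
                        train, shuffling.ShuffleConfig(n_surrogates), rng
                    )
                    method_psds["shuffling"] = corrected
                except Exception as exc:
                    logger.warning("shuffling failed (cell %s rep %s): %s",
                                   cell, rep, exc)
            for method in methods:
                psd = method_psds.get(method)
                if psd is None:
                    labels = np.full((alphas.size, 2), np.nan)
                else:
                    labels = classify_masks(psd, params.f_osc, params.m, alphas)
                    if collect_psds:
                        psds[(cell, rep, method)] = psd.power
                for ai, alpha in enumerate(alphas):
                    rows.append(
                        base | dict(
                            n_r_hat=n_r_hat, method=method, alpha=alpha,
                            hit=labels[ai, 0], fa=labels[ai, 1],
                        )
                    )
        if progress:
            print(f"cell {cell} done", flush=True)
    df = pd.DataFrame(rows)
    if collect_psds:
        df.attrs["psds"] = psds
    return df


def rp_estimates_for_grid(grid: GridSpec, seed: int = 0) -> np.ndarray:
    """RP duration estimates for every train of a grid (NaN on failure).

    Uses the same per-train RNG streams as :func:`run_grid`, so estimates
    match those produced during a full evaluation run.
    """
    out = []
    for cell, params in grid.cells():
        for rep in range(grid.reps):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(cell, rep))
            train = simulate_spike_train(params, np.random.default_rng(ss))
            try:
                out.append(estimate_rp_duration(train).n_r_hat)
            except RpEstimationError:
                out.append(np.nan)
    return np.asarray(out, dtype=float)


def rp_accuracy(n_r_hats, truth: int) -> dict:
    """Percent of estimates with |error| <= 0, 1, 2 ms (failures count as errors)."""
    hats = np.asarray(n_r_hats, dtype=float)
    n = hats.size
    err = np.abs(hats - truth)
    return {
        "exact": 100.0 * float(np.sum(err == 0)) / n,
        "within1": 100.0 * float(np.sum(err <= 1)) / n,
        "within2": 100.0 * float(np.sum(err <= 2)) / n,
    }


def mean_rates_at_alpha(
    results: pd.DataFrame,
    alpha: float = 0.05,
    n_subsamples: int = 100,
    per_cell: int | None = None,
    rng=None,
    methods: tuple = ("residuals", "shuffling"),
) -> dict:
    """Mean hit and FA rates (percent) at one alpha, over ROC subsamples.

    The protocol mirrors the pROC analysis: draw ``per_cell`` trains
    without replacement per m > 0 cell, pool hit/FA rates, and average the
    rates over subsamples. Returns ``{method: {"hr": %, "fa": %}}``.
    """
    if per_cell is None:
        reps = results.groupby("cell")["rep"].nunique().min()
        per_cell = min(20, int(reps))
    hr, fa, alphas = subsample_roc(
        results, n_subsamples=n_subsamples, per_cell=per_cell, rng=rng,
        methods=methods, clamp_per_cell=True,
    )
    ai = int(np.argmin(np.abs(alphas - alpha)))
    return {
        m: {"hr": 100.0 * hr[mi, :, ai].mean(), "fa": 100.0 * fa[mi, :, ai].mean()}
        for mi, m in enumerate(methods)
    }


def matched_reference_rates(
    preset: str, n_trains: int = 100, seed: int = 0, alpha: float = 0.05
) -> dict:
    """Residuals-method hit/FA rates (percent) on matched reference trains.

    Simulates ``n_trains`` non-bursty reference trains from a named preset,
    runs the full residuals pipeline on each, and scores hits (significant
    power within the 3 bins nearest f_osc) and false alarms (significant
    power outside the 10 nearest bins).
    """
    from . import ppm as _ppm
    from .simulate import REFERENCE_PRESETS, simulate_bursty_reference

    params = REFERENCE_PRESETS[preset]
    hits = fas = failures = 0
    for i in range(n_trains):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(i,))
        train = simulate_bursty_reference(preset, np.random.default_rng(ss))
        try:
            psd, _, _ = _ppm.residuals_corrected_psd(train)
        except (RpEstimationError, ValueError):
            failures += 1
            continue
        label = classify_psd(
            significance_test(psd, alpha), params.f_osc, params.m
        )
        hits += label.hit
        fas += label.fa
    scored = n_trains - failures
    return {
        "hit_rate": 100.0 * hits / scored,
        "fa_rate": 100.0 * fas / scored,
        "n": scored,
    }


def matched_reference_isi_stats(
    preset: str, n_trains: int = 100, seed: int = 0, lo: int = 2, hi: int = 3
) -> dict:
    """Mean percent of ISIs, and of consecutive ISI pairs, inside [lo, hi] ms.

    The short-ISI statistics separate genuine burst firing (dense 2-3 ms
    ISIs, often in runs) from what the non-bursty reference process
    produces by chance.
    """
    from .simulate import simulate_bursty_reference

    pct_isi, pct_pair = [], []
    for i in range(n_trains):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(i,))
        train = simulate_bursty_reference(preset, np.random.default_rng(ss))
        isis = train.isis()
        inside = (isis >= lo) & (isis <= hi)
        pct_isi.append(100.0 * inside.mean())
        pct_pair.append(100.0 * (inside[:-1] & inside[1:]).mean())
    return {
        "pct_isi": float(np.mean(pct_isi)),
        "pct_pair": float(np.mean(pct_pair)),
        "n": n_trains,
    }


@dataclass
class RocCurve:
    """One subsample's ROC curve for one method (rates over ALPHA_GRID)."""

    alpha_grid: np.ndarray
    hr: np.ndarray
    fa: np.ndarray
    method: str = ""


def subsample_roc(
    results: pd.DataFrame,
    n_subsamples: int = 1000,
    per_cell: int = 20,
    rng=None,
    methods: tuple = ("residuals", "shuffling"),
    clamp_per_cell: bool = False,
):
    """Subsampled hit/FA rates pooled over the m > 0 cells.

    For each subsample, ``per_cell`` trains are drawn without replacement
    from every m > 0 cell; hit and FA rates are pooled over the drawn
    trains per method and alpha. Trains on which any method failed are
    excluded pairwise before drawing, keeping the comparison paired.

    Returns ``(hr, fa, alphas)`` with arrays of shape
    ``(len(methods), n_subsamples, n_alphas)``.
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    sub = results[results["m"] > 0]
    alphas = np.sort(sub["alpha"].unique())
    # wide: (cell, rep) x (method, alpha)
    wide = sub.pivot_table(
        index=["cell", "rep"], columns=["method", "alpha"],
        values=["hit", "fa"], sort=True,
    )
    wide = wide.dropna(axis=0)  # pairwise exclusion of failed trains
    cells = wide.index.get_level_values("cell")
    unique_cells = cells.unique()
    reps_per_cell = wide.groupby(level="cell").size()
    if (reps_per_cell < per_cell).any():
        if clamp_per_cell:
            per_cell = int(reps_per_cell.min())
        else:
            raise ValueError(
                f"per_cell={per_cell} exceeds available trains in some cell "
                f"(min available: {reps_per_cell.min()})"
            )
    hit_arr = np.stack(
        [wide["hit"][m].reindex(columns=alphas).to_numpy() for m in methods]
    )  # (methods, trains, alphas)
    fa_arr = np.stack(
        [wide["fa"][m].reindex(columns=alphas).to_numpy() for m in methods]
    )
    cell_starts = {c: np.flatnonzero(cells == c) for c in unique_cells}

    hr = np.zeros((len(methods), n_subsamples, alphas.size))
    fa = np.zeros_like(hr)
    for s in range(n_subsamples):
        take = np.concatenate(
            [gen.choice(idx, size=per_cell, replace=False) for idx in cell_starts.values()]
        )
        hr[:, s, :] = hit_arr[:, take, :].mean(axis=1)
        fa[:, s, :] = fa_arr[:, take, :].mean(axis=1)
    return hr, fa, alphas


def _pauc_one(fa: np.ndarray, hr: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal area under one ROC polyline, cropped to FA in [lo, hi].

    The polyline is ordered by increasing alpha; FA is nondecreasing along
    it. Interpolated points are inserted at the crop bounds.
    """
    xs = [lo]
    ys = [float(np.interp(lo, fa, hr))]
    inside = (fa > lo) & (fa < hi)
    xs.extend(fa[inside])
    ys.extend(hr[inside])
    xs.append(hi)
    ys.append(float(np.interp(hi, fa, hr)))
    return float(np.trapezoid(ys, xs))


def pauc_compare(hr: np.ndarray, fa: np.ndarray):
    """Partial-AUC comparison of two methods over matched subsamples.

    ``hr``/``fa`` have shape ``(2, n_subsamples, n_alphas)`` (method 0 is
    the comparison minuend, conventionally residuals). All curves are
    cropped to the intersection of the FA ranges of every curve; the pAUC
    is computed per curve by the trapezoidal rule; a two-tailed paired
    t-test assesses ``D_pAUC = pAUC_0 - pAUC_1 = 0``.

    Returns a dict with per-subsample pAUCs, ``d_pauc``, ``t``, ``p`` and
    the common FA interval.
    """
    if hr.shape[0] != 2:
        raise ValueError("pauc_compare expects exactly two methods")
    n_sub = hr.shape[1]
    if n_sub < 2:
        raise ValueError("need at least 2 subsamples")
    lo = float(fa.min(axis=2).max())
    hi = float(fa.max(axis=2).min())
    if hi <= lo:
        raise ValueError("empty common FA interval across curves")
    paucs = np.zeros((2, n_sub))
    for mi in range(2):
        for s in range(n_sub):
            paucs[mi, s] = _pauc_one(fa[mi, s], hr[mi, s], lo, hi)
    d = paucs[0] - paucs[1]
    if np.allclose(d, 0):
        t_stat, p_val = 0.0, 1.0
    else:
        t_stat, p_val = ttest_rel(paucs[0], paucs[1])
    return {
        "pauc": paucs, "d_pauc": d, "t": float(t_stat), "p": float(p_val),
        "fa_interval": (lo, hi),
    }


def fa_descriptives(
    results: pd.DataFrame, alpha: float = 0.05,
    methods: tuple = ("residuals", "shuffling"),
) -> pd.DataFrame:
    """Peak-power descriptives of false-alarm points.

    For every PSD retained by ``run_grid(..., collect_psds=True)`` that
    contains both hit- and FA-labeled significant points at ``alpha``, the
    ratio of the maximum power among FA points to the maximum among hit
    points is computed, along with the frequency of the FA peak. Values
    are averaged over PSDs within a cell and then over cells, per method.
    """
    psds = results.attrs.get("psds")
    if psds is None:
        raise ValueError("results must carry PSDs (run_grid(collect_psds=True))")
    sub = results[(results["m"] > 0) & np.isclose(results["alpha"], alpha)]
    records = []
    search_freqs = GRID_FREQS[SEARCH_BINS]
    for (cell, rep, method), power in psds.items():
        sel = sub[(sub["cell"] == cell) & (sub["rep"] == rep)
                  & (sub["method"] == method)]
        if sel.empty:
            continue
        f_osc = float(sel["f_osc"].iloc[0])
        psd = Psd(freqs=GRID_FREQS, power=power, n_segments=1)
        sig = significance_test(psd, alpha).sig
        hb = hit_bins(f_osc)
        ex = fa_exempt_bins(f_osc)
        hit_sig = np.zeros_like(sig)
        hit_sig[hb] = sig[hb]
        fa_sig = sig.copy()
        fa_sig[ex] = False
        if not (hit_sig.any() and fa_sig.any()):
            continue
        sp = power[SEARCH_BINS]
        peak_hit = sp[hit_sig].max()
        peak_fa = sp[fa_sig].max()
        records.append(dict(
            cell=cell, method=method,
            peak_ratio=peak_fa / peak_hit,
            peak_fa_freq=search_freqs[fa_sig][np.argmax(sp[fa_sig])],
        ))
    if not records:
        return pd.DataFrame(columns=["method", "peak_ratio", "peak_fa_freq"])
    df = pd.DataFrame(records)
    per_cell = df.groupby(["method", "cell"]).mean(numeric_only=True)
    return per_cell.groupby("method").mean().reset_index()
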