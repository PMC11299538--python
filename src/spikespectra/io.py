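"""Plain-text I/O for spike trains, trial matrices, PSDs and reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SpikeTrain, TrialMatrix
from .spectra import Psd, SignificanceResult

__all__ = [
    "read_timestamps", "write_timestamps",
    "read_delta", "write_delta",
    "read_trial_matrix", "write_trial_matrix",
    "read_psd", "write_psd",
    "write_report",
]


def write_timestamps(train: SpikeTrain, path):
    """One integer spike time (ms, 1-based) per line."""
    times = train.spike_times()
    Path(path).write_text("\n".join(str(int(t)) for t in times) + "\n")


def read_timestamps(path, T: int) -> SpikeTrain:
    text = Path(path).read_text().split()
    times = np.array([int(t) for t in text], dtype=np.int64)
    return SpikeTrain.from_times(times, T)


def write_delta(train: SpikeTrain, path):
    """Delta vector as .npy (compact) or one 0/1 per line (.csv/.txt)."""
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, train.delta.astype(np.uint8))
    else:
        np.savetxt(path, train.delta, fmt="%d")


def read_delta(path) -> SpikeTrain:
    path = Path(path)
    if path.suffix == ".npy":
        return SpikeTrain(np.load(path))
    return SpikeTrain(np.loadtxt(path, dtype=np.uint8))


def write_trial_matrix(trials: TrialMatrix, path):
    np.savetxt(path, trials.dmat, fmt="%d", delimiter=",")


def read_trial_matrix(path) -> TrialMatrix:
    arr = np.loadtxt(path, dtype=np.uint8, delimiter=",", ndmin=2)
    return TrialMatrix(arr)


def write_psd(psd: Psd, path, sig: SignificanceResult | None = None):
    """PSD as CSV with columns freq_hz, power[, significant]."""
    df = pd.DataFrame({"freq_hz": psd.freqs, "power": psd.power})
    if sig is not None:
        flags = np.zeros(psd.freqs.size, dtype=int)
        from .spectra import SEARCH_BINS

        flags[SEARCH_BINS] = sig.sig.astype(int)
        df["significant"] = flags
    df.to_csv(path, index=False)


def write_psd_metadata(psd: Psd, sig: SignificanceResult, path):
    """JSON sidecar with the significance-test parameters and HF statistics."""
    write_report(
        {
            "alpha_c": sig.alpha_c,
            "threshold": sig.threshold,
            "hf_mean": sig.hf_mean,
            "hf_sd": sig.hf_sd,
            "n_segments": psd.n_segments,
            "n_significant": int(sig.sig.sum()),
        },
        path,
    )


def read_psd(path) -> Psd:
    df = pd.read_csv(path)
    return Psd(freqs=df["freq_hz"].to_numpy(), power=df["power"].to_numpy(),
               n_segments=0)


def write_report(obj: dict, path):
    """JSON report with numpy types coerced to plain Python."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
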