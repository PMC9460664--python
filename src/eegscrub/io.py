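"""Reading and writing signals, mode/source matrices, and sidecar JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .signal import Signal
from .sobi import MultichannelData, SobiResult
from .vmd import ModeSet

__all__ = [
    "read_signal_csv",
    "write_signal_csv",
    "read_matrix_csv",
    "write_modes_csv",
    "write_sources_csv",
    "read_edf",
]


def read_signal_csv(path, fs: float) -> Signal:
    """Load a single-column numeric text/CSV file (optional header row)."""
    df = pd.read_csv(path, header=None, comment="#")
    if df.shape[1] != 1:
        raise InvalidInputError(
            f"{path}: expected a single column, found {df.shape[1]}"
        )
    col = df.iloc[:, 0]
    if not pd.api.types.is_numeric_dtype(col):
        col = pd.to_numeric(col.iloc[1:], errors="raise")  # drop header row
    return Signal(col.to_numpy(dtype=float), fs=fs)


def write_signal_csv(path, signal: Signal) -> None:
    np.savetxt(path, signal.samples, fmt="%.10g")


def read_matrix_csv(path, fs: float) -> MultichannelData:
    """Load a multi-column CSV (columns = channels, header row allowed)."""
    df = pd.read_csv(path)
    try:
        arr = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise InvalidInputError(f"{path}: non-numeric matrix") from exc
    return MultichannelData(arr.T, fs=fs)


def write_modes_csv(path, modes: ModeSet, sidecar_path=None) -> None:
    """One column per mode (header ``imf1..imfK``); center frequencies and
    iteration bookkeeping go to a JSON sidecar when requested."""
    k = modes.k
    df = pd.DataFrame(modes.modes.T, columns=[f"imf{i + 1}" for i in range(k)])
    df.to_csv(path, index=False, float_format="%.10g")
    if sidecar_path is not None:
        payload = {
            "center_freqs": [float(w) for w in modes.center_freqs],
            "center_freqs_hz": [float(w) for w in modes.center_freqs_hz],
            "fs": modes.fs,
            "n_iters": modes.n_iters,
            "converged": modes.converged,
        }
        Path(sidecar_path).write_text(json.dumps(payload, indent=2))


def write_sources_csv(path, result: SobiResult, matrices_path=None) -> None:
    """Separated components as ``ic1..icm`` columns; mixing and whitening
    matrices as JSON when requested."""
    m = result.n_components
    df = pd.DataFrame(result.sources.T, columns=[f"ic{i + 1}" for i in range(m)])
    df.to_csv(path, index=False, float_format="%.10g")
    if matrices_path is not None:
        payload = {
            "whitening": result.whitening.tolist(),
            "rotation": result.rotation.tolist(),
            "mixing": result.mixing.tolist(),
            "channel_means": result.channel_means.tolist(),
            "n_sweeps": result.n_sweeps,
        }
        Path(matrices_path).write_text(json.dumps(payload, indent=2))


def read_edf(path, channel: str | int = 0) -> Signal:
    """Load one channel of an EDF recording (requires the optional
    ``pyedflib`` dependency)."""
    try:
        import pyedflib
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF support requires the optional 'pyedflib' package"
        ) from exc
    with pyedflib.EdfReader(str(path)) as reader:  # pragma: no cover
        labels = reader.getSignalLabels()
        idx = labels.index(channel) if isinstance(channel, str) else int(channel)
        data = reader.readSignal(idx)
        fs = reader.getSampleFrequency(idx)
    return Signal(data, fs=fs)  # pragma: no cover
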