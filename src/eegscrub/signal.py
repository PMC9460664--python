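"""Core :class:`Signal` container for single-channel time series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = ["Signal"]


@dataclass(frozen=True)
class Signal:
    """A finite, real-valued, uniformly sampled sequence.

    Parameters
    ----------
    samples
        Amplitude values (arbitrary units, typically microvolts). Coerced to
        a read-only ``float64`` array.
    fs
        Sampling rate in Hz. Must be positive.
    """

    samples: np.ndarray
    fs: float = field(default=1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1:
            raise InvalidInputError("signal must be one-dimensional")
        if arr.size < 2:
            raise InvalidInputError("signal must contain at least 2 samples")
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("signal contains non-finite samples")
        if not (self.fs > 0 and np.isfinite(self.fs)):
            raise InvalidInputError(f"sampling rate must be positive, got {self.fs}")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "fs", float(self.fs))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds starting at 0."""
        return np.arange(self.samples.size) / self.fs

    def power(self) -> float:
        """Mean squared amplitude."""
        return float(np.mean(self.samples**2))
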