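"""Variational Mode Decomposition (VMD).

Decomposes a single-channel signal into ``K`` narrow-band modes by
alternating frequency-domain Wiener-filter updates of the mode spectra with
power-weighted-mean updates of their center frequencies, under an augmented
Lagrangian whose multiplier is updated with weight ``gamma``.

All spectral work happens on the non-negative half-spectrum (``rfft``); the
time-domain modes are recovered with the conjugate-symmetric inverse
transform.  Center frequencies are stored normalized (cycles/sample,
``[0, 0.5)``); multiply by ``fs`` for Hz.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidConfigError, InvalidInputError
from .signal import Signal

__all__ = [
    "VmdConfig",
    "ModeSet",
    "vmd_decompose",
    "reconstruct",
    "fixed_centers_hz",
    "default_config",
]

#: Default fixed initial center frequencies, in Hz (converted by the input fs).
DEFAULT_INIT_HZ = (5.0, 30.0, 150.0)

# Largest representable normalized frequency strictly below Nyquist.
_MAX_NORM_FREQ = np.nextafter(0.5, 0.0)


def fixed_centers_hz(freqs_hz: Sequence[float], fs: float) -> tuple[float, ...]:
    """Convert center frequencies in Hz to normalized units, clipping into
    ``[0, 0.5)``.

    Values at or above the Nyquist frequency are clipped to just below 0.5
    (the analysis band has no room above it).
    """
    out = []
    for f in freqs_hz:
        w = f / fs
        if w < 0:
            raise InvalidConfigError(f"negative center frequency {f} Hz")
        out.append(min(w, _MAX_NORM_FREQ))
    return tuple(out)


def default_config(fs: float, k: int = 3) -> "VmdConfig":
    """Default decomposition config: K=3, alpha=1500, gamma=0, eps=1e-5,
    fixed initial centers {5, 30, 150} Hz converted by ``fs`` (clipped to
    the analysis band)."""
    if k == len(DEFAULT_INIT_HZ):
        init: str | tuple[float, ...] = fixed_centers_hz(DEFAULT_INIT_HZ, fs)
    else:
        init = "zeros"
    return VmdConfig(k=k, init_centers=init)


@dataclass(frozen=True)
class VmdConfig:
    """Parameters of the decomposition.

    ``init_centers`` selects the initialization scheme for the center
    frequencies: ``"zeros"`` (all 0), ``"random"`` (K uniform draws in
    (0, 0.5) from ``seed``, sorted), or an explicit sequence of K normalized
    frequencies in ``[0, 0.5)``.
    """

    k: int = 3
    alpha: float = 1500.0
    gamma: float = 0.0
    epsilon: float = 1e-5
    init_centers: str | tuple[float, ...] = "zeros"
    seed: int | None = None
    max_iters: int = 500
    mirror: bool = True

    def __post_init__(self) -> None:
        if not (isinstance(self.k, (int, np.integer)) and self.k >= 1):
            raise InvalidConfigError(f"K must be an integer >= 1, got {self.k}")
        if not self.alpha > 0:
            raise InvalidConfigError("alpha must be positive")
        if not 0.0 <= self.gamma <= 1.0:
            raise InvalidConfigError("gamma must lie in [0, 1]")
        if not self.epsilon > 0:
            raise InvalidConfigError("epsilon must be positive")
        if not (isinstance(self.max_iters, (int, np.integer)) and self.max_iters >= 1):
            raise InvalidConfigError("max_iters must be a positive integer")
        if isinstance(self.init_centers, str):
            if self.init_centers not in ("zeros", "random"):
                raise InvalidConfigError(
                    f"unknown init scheme {self.init_centers!r}; "
                    "use 'zeros', 'random' or an explicit frequency tuple"
                )
        else:
            centers = tuple(float(w) for w in self.init_centers)
            if len(centers) != self.k:
                raise InvalidConfigError(
                    f"fixed init needs exactly K={self.k} entries, got {len(centers)}"
                )
            if any(not (0.0 <= w < 0.5) for w in centers):
                raise InvalidConfigError("fixed init centers must lie in [0, 0.5)")
            object.__setattr__(self, "init_centers", centers)

    def with_k(self, k: int) -> "VmdConfig":
        """Copy of this config with a different mode count.

        An explicit fixed-center list only makes sense for its own K, so it
        falls back to the ``zeros`` scheme when the count changes.
        """
        init = self.init_centers
        if not isinstance(init, str) and len(init) != k:
            init = "zeros"
        return dataclasses.replace(self, k=k, init_centers=init)


@dataclass(frozen=True)
class ModeSet:
    """Result of a decomposition: K modes plus bookkeeping.

    ``modes`` has shape ``(K, T)``; row ``k`` is the time-domain mode.
    ``center_freqs`` are normalized (cycles/sample), ascending.
    """

    modes: np.ndarray
    center_freqs: np.ndarray
    fs: float
    n_iters: int
    converged: bool

    @property
    def k(self) -> int:
        return self.modes.shape[0]

    @property
    def center_freqs_hz(self) -> np.ndarray:
        return self.center_freqs * self.fs


def _init_omegas(cfg: VmdConfig) -> np.ndarray:
    if isinstance(cfg.init_centers, str):
        if cfg.init_centers == "zeros":
            return np.zeros(cfg.k)
        rng = np.random.default_rng(cfg.seed)
        draws = rng.uniform(0.0, 0.5, size=cfg.k)
        # strictly inside (0, 0.5): redraw exact zeros (probability ~0)
        draws[draws == 0.0] = 0.25
        return np.sort(draws)
    return np.asarray(cfg.init_centers, dtype=float)


def vmd_decompose(signal: Signal, cfg: VmdConfig | None = None) -> ModeSet:
    """Decompose ``signal`` into ``cfg.k`` band-limited modes.

    Iterates, until the summed relative spectral change of the modes drops
    below ``cfg.epsilon`` or ``cfg.max_iters`` is reached:

    1. per-mode Wiener update
       ``u_k <- (f - sum_{i != k} u_i + lam/2) / (1 + 2 alpha (w - w_k)^2)``
    2. center-frequency update ``w_k <- <w |u_k|^2> / <|u_k|^2>``
       (unchanged if the mode carries zero energy)
    3. multiplier update ``lam <- lam + gamma (f - sum_k u_k)``

    Returns modes sorted by ascending center frequency.  Hitting the
    iteration cap is not an error: ``converged`` is simply ``False``.

    When ``cfg`` is omitted, the default uses the fixed initial centers
    :data:`DEFAULT_INIT_HZ` converted by the signal's sampling rate.
    """
    if cfg is None:
        cfg = default_config(signal.fs)
    x = signal.samples
    T = x.size
    if cfg.k > T // 2:
        raise InvalidConfigError(
            f"K={cfg.k} too large for signal of length {T} (need K <= length/2)"
        )

    if cfg.mirror and T >= 2:
        half = T // 2
        ext = np.concatenate([x[:half][::-1], x, x[T - half :][::-1]])
        lo = half
    else:
        ext = x
        lo = 0
    n_ext = ext.size

    freqs = np.fft.rfftfreq(n_ext)  # normalized, in [0, 0.5]
    f_hat = np.fft.rfft(ext)
    K = cfg.k
    alpha = cfg.alpha

    omega = _init_omegas(cfg)
    u_hat = np.zeros((K, freqs.size), dtype=complex)
    lam_hat = np.zeros(freqs.size, dtype=complex)

    # eps floor keeps the convergence statistic finite when a mode starts
    # from zero energy (first iteration from the all-zeros init)
    tiny = np.finfo(float).eps
    converged = False
    n_iters = 0
    sum_u = u_hat.sum(axis=0)
    for n_iters in range(1, cfg.max_iters + 1):
        u_prev = u_hat.copy()
        for k in range(K):
            sum_u -= u_hat[k]
            u_hat[k] = (f_hat - sum_u + lam_hat / 2.0) / (
                1.0 + 2.0 * alpha * (freqs - omega[k]) ** 2
            )
            sum_u += u_hat[k]
            power = np.abs(u_hat[k]) ** 2
            denom = power.sum()
            if denom > 0.0:
                omega[k] = float(np.dot(freqs, power) / denom)
        if cfg.gamma != 0.0:
            lam_hat = lam_hat + cfg.gamma * (f_hat - sum_u)

        diff = np.abs(u_hat - u_prev) ** 2
        prev_energy = (np.abs(u_prev) ** 2).sum(axis=1)
        stat = float((diff.sum(axis=1) / (prev_energy + tiny)).sum())
        if stat < cfg.epsilon:
            converged = True
            break

    modes_ext = np.fft.irfft(u_hat, n=n_ext, axis=1)
    modes = modes_ext[:, lo : lo + T]

    omega = np.clip(omega, 0.0, _MAX_NORM_FREQ)
    order = np.lexsort((np.arange(K), omega))
    return ModeSet(
        modes=np.ascontiguousarray(modes[order]),
        center_freqs=omega[order],
        fs=signal.fs,
        n_iters=n_iters,
        converged=converged,
    )


def reconstruct(modes: ModeSet) -> Signal:
    """Sum the modes back into a single signal (the decomposition constraint
    requires the modes to add up to the input; with ``gamma=0`` a small
    residual is lost)."""
    rows = list(np.asarray(m, dtype=float) for m in modes.modes)
    if len(rows) == 0:
        raise InvalidInputError("empty ModeSet")
    length = rows[0].size
    if any(r.ndim != 1 or r.size != length for r in rows):
        raise InvalidInputError("modes have unequal lengths")
    total = np.sum(rows, axis=0)
    return Signal(total, fs=modes.fs)
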