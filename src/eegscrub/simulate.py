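"""Seeded semi-simulation fixtures.

Builds contaminated test records ``X = X_eeg + theta * X_artifact`` from
band-limited noise surrogates (EOG-band drift with blink-like bumps,
EEG-band activity, EMG-band noise), with ``theta`` solved so the mixture
hits a requested signal-to-artifact SNR.  Everything is a pure function of
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidConfigError, InvalidInputError
from .signal import Signal

__all__ = ["SimConfig", "SemiSimulation", "make_component", "mix", "semi_simulate", "snr_sweep"]

EOG_BAND = (0.0, 5.0)
EEG_BAND = (10.0, 50.0)
EMG_BAND_LO = 80.0  # upper edge is Nyquist


@dataclass(frozen=True)
class SimConfig:
    """Semi-simulation parameters; bands default to the EOG/EEG/EMG ranges
    0-5, 10-50, and 80-Nyquist Hz."""

    fs: float = 250.0
    duration_s: float = 8.0
    seed: int = 0
    snr_db: float = -1.0
    eog_band: tuple[float, float] = EOG_BAND
    eeg_band: tuple[float, float] = EEG_BAND
    emg_band: tuple[float, float] | None = None  # None -> (80, fs/2)
    include_eog: bool = True
    include_emg: bool = True

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise InvalidConfigError("fs and duration must be positive")
        if self.fs * self.duration_s < 512:
            raise InvalidConfigError("need at least 512 samples (fs * duration)")
        if self.emg_band is None:
            object.__setattr__(
                self, "emg_band", (min(EMG_BAND_LO, self.fs / 2 * 0.9), self.fs / 2)
            )
        for band in (self.eog_band, self.eeg_band, self.emg_band):
            _check_band(band, self.fs)
        if not (self.include_eog or self.include_emg):
            raise InvalidConfigError("at least one artifact type must be included")


def _check_band(band: tuple[float, float], fs: float) -> None:
    lo, hi = band
    if not (0 <= lo < hi):
        raise InvalidConfigError(f"band {band} must satisfy 0 <= lo < hi")
    if hi > fs / 2:
        raise InvalidConfigError(f"band {band} exceeds Nyquist ({fs / 2} Hz)")


def make_component(
    band: tuple[float, float],
    fs: float,
    duration_s: float,
    seed,
    kind: str = "noise",
) -> Signal:
    """Zero-mean, unit-variance stochastic signal strictly band-limited to
    ``band`` (brick-wall spectral masking of white noise, so out-of-band
    power is exactly zero).

    ``kind="eog"`` adds slow blink-like bumps before the band mask, giving
    the low-frequency surrogate its characteristic spiky envelope.
    ``kind="eeg"`` weights the in-band spectrum by ``1/f`` (relative to the
    lower band edge) so the surrogate concentrates its power toward the low
    end of the band the way cortical activity does, instead of being
    unrealistically flat across it.
    """
    _check_band(band, fs)
    n = int(round(fs * duration_s))
    if n < 4:
        raise InvalidConfigError("duration too short")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    if kind == "eog":
        t = np.arange(n) / fs
        n_blinks = max(1, int(duration_s / 2.0))
        centers = rng.uniform(0.2, duration_s - 0.2, size=n_blinks)
        widths = rng.uniform(0.08, 0.2, size=n_blinks)
        amps = rng.uniform(4.0, 8.0, size=n_blinks)
        for c, w, a in zip(centers, widths, amps):
            x = x + a * np.exp(-0.5 * ((t - c) / w) ** 2)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    mask[0] = False  # always remove DC: components are zero-mean
    if not mask.any():
        raise InvalidConfigError(f"band {band} contains no Fourier bins at length {n}")
    spec[~mask] = 0.0
    if kind == "eeg":
        ref = max(band[0], freqs[mask].min())
        spec[mask] *= (freqs[mask] / ref) ** -1.0
    y = np.fft.irfft(spec, n=n)
    sd = y.std()
    if sd == 0.0:
        raise InvalidConfigError(f"band {band} produced a degenerate component")
    return Signal(y / sd, fs=fs)


def mix(
    eeg: Signal, artifacts: Sequence[Signal], snr_db: float
) -> tuple[Signal, float]:
    """Scale the summed artifacts by ``theta`` so that
    ``10 log10(P_eeg / P_(theta * artifact)) = snr_db`` and add them to the
    clean component.  Returns ``(mixture, theta)``."""
    arts = [np.asarray(a.samples, dtype=float) for a in artifacts]
    if not arts:
        raise InvalidInputError("need at least one artifact")
    if any(a.size != len(eeg) for a in arts):
        raise InvalidInputError("artifact lengths must match the clean signal")
    total_art = np.sum(arts, axis=0)
    p_art = float(np.mean(total_art**2))
    if p_art == 0.0:
        raise InvalidInputError("artifact power is zero")
    p_eeg = eeg.power()
    theta = float(np.sqrt(p_eeg / (p_art * 10.0 ** (snr_db / 10.0))))
    return Signal(eeg.samples + theta * total_art, fs=eeg.fs), theta


@dataclass(frozen=True)
class SemiSimulation:
    """One generated fixture: the mixture, its clean and artifact parts,
    and the artifact scale actually applied."""

    mixture: Signal
    eeg: Signal
    eog: Signal | None
    emg: Signal | None
    theta: float
    config: SimConfig

    @property
    def artifact(self) -> Signal:
        """Scaled total artifact waveform (mixture minus clean part)."""
        return Signal(self.mixture.samples - self.eeg.samples, fs=self.mixture.fs)


def semi_simulate(cfg: SimConfig) -> SemiSimulation:
    """Generate the full fixture from a config (pure function of it)."""
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.spawn(3)
    eeg = make_component(cfg.eeg_band, cfg.fs, cfg.duration_s, seeds[0], kind="eeg")
    artifacts = []
    eog = emg = None
    if cfg.include_eog:
        eog = make_component(cfg.eog_band, cfg.fs, cfg.duration_s, seeds[1], kind="eog")
        artifacts.append(eog)
    if cfg.include_emg:
        emg = make_component(cfg.emg_band, cfg.fs, cfg.duration_s, seeds[2])
        artifacts.append(emg)
    mixture, theta = mix(eeg, artifacts, cfg.snr_db)
    return SemiSimulation(
        mixture=mixture, eeg=eeg, eog=eog, emg=emg, theta=theta, config=cfg
    )


def snr_sweep(
    snrs_db: Sequence[float], seed: int = 0, **cfg_kwargs
) -> list[SemiSimulation]:
    """One fixture per requested SNR, each with a distinct child seed.

    The evaluation sweep -1.5..1.5 dB in 0.5 steps and the wider
    convergence-study sweep -12..8 dB are both single calls here.
    """
    snrs = [float(s) for s in snrs_db]
    child_seeds = np.random.SeedSequence(seed).generate_state(len(snrs))
    return [
        semi_simulate(SimConfig(seed=int(s), snr_db=snr, **cfg_kwargs))
        for snr, s in zip(snrs, child_seeds)
    ]
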