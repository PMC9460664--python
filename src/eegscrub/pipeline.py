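"""End-to-end artifact removal and evaluation metrics.

Flow: decompose the single channel into modes, separate the mode matrix
into source components, score each component's complexity with fuzzy
entropy, label/zero the artifact components, back-project through the
mixing matrix, and sum the cleaned channels into one signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .errors import InvalidInputError, UndefinedMetricError
from .fuzzyent import FeConfig, fuzzy_entropy
from .kselect import K_RANGE_DEFAULT, KSelectionTrace, select_k
from .signal import Signal
from .sobi import MultichannelData, SobiConfig, SobiResult, sobi_separate
from .vmd import ModeSet, VmdConfig, default_config, reconstruct, vmd_decompose

__all__ = [
    "ArtifactLabeling",
    "Metrics",
    "ExtremesPolicy",
    "ThresholdPolicy",
    "label_from_scores",
    "label_components",
    "remove_and_reconstruct",
    "compute_metrics",
    "run_pipeline",
    "PipelineResult",
]

logger = logging.getLogger(__name__)

LABEL_EEG = "EEG"
LABEL_EOG = "EOG"
LABEL_EMG = "EMG"


@dataclass(frozen=True)
class ExtremesPolicy:
    """Label the minimum-entropy component EOG and the maximum EMG.

    With ``spectral_veto`` on, a candidate label is dropped (component kept
    as EEG, warning logged) unless the component's spectrum is actually
    dominated by the corresponding band: more than ``dominance`` of its
    power below ``eog_max_hz`` for EOG, above ``emg_min_hz`` for EMG.
    """

    spectral_veto: bool = True
    eog_max_hz: float = 5.0
    emg_min_hz: float = 45.0
    dominance: float = 0.5


@dataclass(frozen=True)
class ThresholdPolicy:
    """Two-threshold labeling for component counts other than 3: scores
    below ``low`` become EOG, above ``high`` EMG, the rest EEG."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise InvalidInputError("threshold policy needs low < high")


@dataclass(frozen=True)
class ArtifactLabeling:
    """Per-component entropy scores, category labels, and removal mask."""

    fe_scores: tuple[float, ...]
    labels: tuple[str, ...]
    removal_mask: tuple[bool, ...]

    def __post_init__(self) -> None:
        n = len(self.fe_scores)
        if not (len(self.labels) == len(self.removal_mask) == n):
            raise InvalidInputError("labeling fields must have equal lengths")
        if all(self.removal_mask):
            raise InvalidInputError("at least one component must be retained")
        for label, masked in zip(self.labels, self.removal_mask):
            if label not in (LABEL_EEG, LABEL_EOG, LABEL_EMG):
                raise InvalidInputError(f"unknown label {label!r}")
            if masked and label == LABEL_EEG:
                raise InvalidInputError("an EEG-labeled component cannot be removed")


def label_from_scores(
    scores: Sequence[float],
    policy: ExtremesPolicy | ThresholdPolicy | None = None,
) -> ArtifactLabeling:
    """Assign EEG/EOG/EMG labels from fuzzy-entropy scores alone.

    Extremes policy: the minimum-score component is EOG, the maximum EMG,
    everything else EEG; ties are broken toward the lower index keeping its
    EEG label (a warning is logged).  With only 2 components just the
    higher-score one is treated as artifact (EMG) so something is retained.
    """
    if policy is None:
        policy = ExtremesPolicy()
    scores = tuple(float(s) for s in scores)
    n = len(scores)
    if n < 2:
        raise InvalidInputError("need at least 2 components to label")

    labels = [LABEL_EEG] * n
    if isinstance(policy, ThresholdPolicy):
        for i, s in enumerate(scores):
            if s < policy.low:
                labels[i] = LABEL_EOG
            elif s > policy.high:
                labels[i] = LABEL_EMG
        if all(l != LABEL_EEG for l in labels):
            keep = int(np.argsort(scores)[n // 2])
            logger.warning(
                "threshold policy labeled every component an artifact; "
                "keeping component %d as EEG", keep + 1,
            )
            labels[keep] = LABEL_EEG
    else:
        if len(set(scores)) < n:
            logger.warning("tied fuzzy-entropy scores; ties broken by component index")
        i_min = int(np.argmin(scores))
        i_max = int(np.argmax(scores))
        if i_min == i_max:  # all scores equal
            i_max = n - 1 if i_min != n - 1 else n - 2
        if n == 2:
            labels[max(i_min, i_max) if scores[0] == scores[1] else i_max] = LABEL_EMG
        else:
            labels[i_min] = LABEL_EOG
            labels[i_max] = LABEL_EMG

    mask = tuple(l != LABEL_EEG for l in labels)
    return ArtifactLabeling(fe_scores=scores, labels=tuple(labels), removal_mask=mask)


def _band_fraction(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    total = spec.sum()
    if total == 0.0:
        return 0.0
    return float(spec[(freqs >= lo) & (freqs <= hi)].sum() / total)


def label_components(
    sources: MultichannelData | np.ndarray,
    fe_cfg: FeConfig | None = None,
    policy: ExtremesPolicy | ThresholdPolicy | None = None,
    fs: float | None = None,
) -> ArtifactLabeling:
    """Score each separated component with fuzzy entropy and label it.

    Under the default extremes policy the spectral veto can overturn a
    candidate artifact label when the component's power is not dominated by
    the expected band (EOG below ~5 Hz, EMG above ~45 Hz).
    """
    if isinstance(sources, MultichannelData):
        arr = sources.channels
        fs = sources.fs
    else:
        arr = np.atleast_2d(np.asarray(sources, dtype=float))
    if arr.shape[0] < 2:
        raise InvalidInputError("need at least 2 components")
    if fe_cfg is None:
        fe_cfg = FeConfig()
    if policy is None:
        policy = ExtremesPolicy()

    scores = [fuzzy_entropy(row, fe_cfg) for row in arr]
    labeling = label_from_scores(scores, policy)

    if isinstance(policy, ExtremesPolicy) and policy.spectral_veto and fs is not None:
        labels = list(labeling.labels)
        for i, label in enumerate(labels):
            if label == LABEL_EOG:
                frac = _band_fraction(arr[i], fs, 0.0, policy.eog_max_hz)
                if frac <= policy.dominance:
                    logger.warning(
                        "spectral veto: component %d labeled EOG but only %.1f%% of "
                        "its power lies below %g Hz; keeping it",
                        i + 1, 100 * frac, policy.eog_max_hz,
                    )
                    labels[i] = LABEL_EEG
            elif label == LABEL_EMG:
                frac = _band_fraction(arr[i], fs, policy.emg_min_hz, fs / 2)
                if frac <= policy.dominance:
                    logger.warning(
                        "spectral veto: component %d labeled EMG but only %.1f%% of "
                        "its power lies above %g Hz; keeping it",
                        i + 1, 100 * frac, policy.emg_min_hz,
                    )
                    labels[i] = LABEL_EEG
        mask = tuple(l != LABEL_EEG for l in labels)
        labeling = ArtifactLabeling(
            fe_scores=labeling.fe_scores, labels=tuple(labels), removal_mask=mask
        )
    return labeling


def remove_and_reconstruct(
    modes: ModeSet, sobi: SobiResult, labeling: ArtifactLabeling
) -> Signal:
    """Zero the masked source components, back-project through the mixing
    matrix, and sum the cleaned mode channels into one signal.

    The channel means removed before whitening are carried by the source
    components themselves (via the inverse transform of the mean vector);
    masked components take their share of the mean with them.
    """
    m = sobi.n_components
    if len(labeling.removal_mask) != m:
        raise InvalidInputError("labeling size does not match the separation")
    if modes.modes.shape[0] != m:
        raise InvalidInputError("mode count does not match the separation")

    # full (uncentered) sources: y_full = V^T Q x = sources + V^T Q mean
    mean_src = sobi.rotation.T @ sobi.whitening @ sobi.channel_means
    keep = ~np.asarray(labeling.removal_mask, dtype=bool)
    y_clean = sobi.sources * keep[:, None] + (mean_src * keep)[:, None]
    cleaned_channels = sobi.mixing @ y_clean
    return Signal(cleaned_channels.sum(axis=0), fs=modes.fs)


@dataclass(frozen=True)
class Metrics:
    """Signal-to-noise ratio (dB), relative RMS error, and Pearson
    correlation between a reference and an estimate."""

    snr_db: float
    rrmse: float
    cc: float


def compute_metrics(reference: Signal, estimate: Signal) -> Metrics:
    """Evaluate an estimate against the reference.

    ``snr_db = 10 log10(sum(x^2) / sum((y - x)^2))``,
    ``rrmse = sqrt(sum((y - x)^2) / sum(x^2))``, and ``cc`` is the Pearson
    correlation.  Identical inputs give ``snr_db = +inf``, ``rrmse = 0``,
    ``cc = 1``.
    """
    x = reference.samples
    y = estimate.samples
    if x.size != y.size:
        raise InvalidInputError("reference and estimate lengths differ")
    ref_energy = float(np.sum(x**2))
    if ref_energy == 0.0:
        raise UndefinedMetricError("reference signal has zero energy")
    err_energy = float(np.sum((y - x) ** 2))
    if err_energy == 0.0:
        return Metrics(snr_db=math.inf, rrmse=0.0, cc=1.0)
    snr_db = 10.0 * math.log10(ref_energy / err_energy)
    rrmse = math.sqrt(err_energy / ref_energy)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(np.sum(xc**2) * np.sum(yc**2)))
    if denom == 0.0:
        raise UndefinedMetricError("a constant signal has no correlation")
    cc = float(np.dot(xc, yc) / denom)
    return Metrics(snr_db=snr_db, rrmse=rrmse, cc=max(-1.0, min(1.0, cc)))


class PipelineResult(NamedTuple):
    cleaned: Signal
    labeling: ArtifactLabeling
    modes: ModeSet
    sobi: SobiResult
    k_trace: KSelectionTrace | None


def run_pipeline(
    signal: Signal,
    vmd_cfg: VmdConfig | None = None,
    sobi_cfg: SobiConfig | None = None,
    fe_cfg: FeConfig | None = None,
    policy: ExtremesPolicy | ThresholdPolicy | None = None,
    auto_k: bool = False,
    k_range: tuple[int, int] = K_RANGE_DEFAULT,
) -> PipelineResult:
    """Full artifact removal on one channel.

    With ``auto_k=True`` the mode count is chosen first by the
    invalid-center-frequency rule (falling back to the top of ``k_range``
    when it never triggers); otherwise ``vmd_cfg.k`` is used as given.
    Deterministic given the configs and seeds.
    """
    if vmd_cfg is None:
        vmd_cfg = default_config(signal.fs)
    k_trace = None
    if auto_k:
        k_trace = select_k(signal, vmd_cfg, k_range=k_range)
        k = k_trace.selected_k if k_trace.selected_k is not None else k_trace.fallback_k
        logger.info("automatic mode-count selection chose K=%d", k)
        vmd_cfg = vmd_cfg.with_k(k)

    modes = vmd_decompose(signal, vmd_cfg)
    data = MultichannelData(modes.modes, fs=signal.fs)
    sep = sobi_separate(data, sobi_cfg)
    labeling = label_components(
        MultichannelData(sep.sources, fs=signal.fs), fe_cfg, policy
    )
    logger.info(
        "component labels: %s (FE scores %s)",
        labeling.labels,
        ["%.4g" % s for s in labeling.fe_scores],
    )
    cleaned = remove_and_reconstruct(modes, sep, labeling)
    return PipelineResult(
        cleaned=cleaned, labeling=labeling, modes=modes, sobi=sep, k_trace=k_trace
    )
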