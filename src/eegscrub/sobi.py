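"""Second Order Blind Identification (SOBI).

Separates an ``m``-channel record into source components using only
second-order statistics: mean-center, whiten, estimate time-lagged
covariance matrices, and jointly diagonalize them with Givens-rotation
sweeps.  The estimated mixing matrix is ``A = Q^-1 V`` and the sources are
``y = V^T Q x``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, InvalidConfigError, InvalidInputError

__all__ = [
    "MultichannelData",
    "SobiConfig",
    "SobiResult",
    "whiten",
    "lagged_covariances",
    "joint_diagonalize",
    "sobi_separate",
]


@dataclass(frozen=True)
class MultichannelData:
    """Channels-by-samples real matrix with a sampling rate."""

    channels: np.ndarray
    fs: float = 1.0

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if arr.ndim != 2:
            raise InvalidInputError("channels must form a 2-D array")
        m, t = arr.shape
        if m < 2:
            raise InvalidInputError(f"need at least 2 channels, got {m}")
        if t <= m:
            raise InvalidInputError(f"need more samples ({t}) than channels ({m})")
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("non-finite values in channels")
        if not self.fs > 0:
            raise InvalidInputError("sampling rate must be positive")
        object.__setattr__(self, "channels", arr)

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]


def default_lags(n_samples: int) -> tuple[int, ...]:
    """Default delay set: 1..min(100, T//4)."""
    return tuple(range(1, min(100, n_samples // 4) + 1))


@dataclass(frozen=True)
class SobiConfig:
    """Separation parameters.

    ``lags`` may be ``None``, meaning :func:`default_lags` of the input
    length.  ``ridge`` adds ``ridge * max_eigenvalue`` to the covariance
    diagonal before whitening (off by default).
    """

    lags: tuple[int, ...] | None = None
    jd_tolerance: float = 1e-8
    max_sweeps: int = 100
    ridge: float = 0.0

    def __post_init__(self) -> None:
        if self.lags is not None:
            lags = tuple(int(t) for t in self.lags)
            if not lags:
                raise InvalidConfigError("lag set must be non-empty")
            if any(t <= 0 for t in lags):
                raise InvalidConfigError("lags must be positive integers")
            object.__setattr__(self, "lags", lags)
        if not self.jd_tolerance > 0:
            raise InvalidConfigError("jd_tolerance must be positive")
        if self.max_sweeps < 1:
            raise InvalidConfigError("max_sweeps must be >= 1")
        if self.ridge < 0:
            raise InvalidConfigError("ridge must be non-negative")


@dataclass(frozen=True)
class SobiResult:
    """Whitening matrix ``Q``, orthogonal rotation ``V``, mixing
    ``A = Q^-1 V``, separated sources ``y = V^T Q (x - mean)``, and the
    channel means removed during centering."""

    whitening: np.ndarray
    rotation: np.ndarray
    mixing: np.ndarray
    sources: np.ndarray
    channel_means: np.ndarray
    fs: float
    n_sweeps: int = 0

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]


# rank-deficiency cutoff relative to the largest covariance eigenvalue
_RANK_RTOL = 1e-12


def whiten(
    data: MultichannelData, ridge: float = 0.0
) -> tuple[np.ndarray, MultichannelData]:
    """Mean-center and decorrelate: returns ``(Q, z)`` with
    ``z = Q (x - mean)`` having identity sample covariance.

    Raises :class:`DegenerateInputError` when the sample covariance is
    rank-deficient and ``ridge`` is zero.
    """
    x = data.channels
    xc = x - x.mean(axis=1, keepdims=True)
    cov = xc @ xc.T / (data.n_samples - 1)
    if ridge > 0.0:
        cov = cov + ridge * float(np.trace(cov)) / data.n_channels * np.eye(
            data.n_channels
        )
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0 or evals[0] <= _RANK_RTOL * evals[-1]:
        raise DegenerateInputError(
            "channel covariance is rank-deficient; enable ridge regularization"
        )
    q = (evecs / np.sqrt(evals)).T  # diag(evals^-1/2) @ evecs.T
    z = q @ xc
    return q, MultichannelData(z, fs=data.fs)


def lagged_covariances(
    whitened: MultichannelData, lags: Sequence[int]
) -> list[np.ndarray]:
    """Sample covariance ``R(tau) = E[z(t+tau) z(t)^T]`` for each delay,
    symmetrized as ``(R + R^T)/2``."""
    z = whitened.channels
    t = whitened.n_samples
    out = []
    for tau in lags:
        tau = int(tau)
        if tau >= t:
            raise InvalidConfigError(f"lag {tau} >= record length {t}")
        if tau < 0:
            raise InvalidConfigError("lags must be non-negative")
        if tau == 0:
            r = z @ z.T / (t - 1)
        else:
            r = z[:, tau:] @ z[:, :-tau].T / (t - tau)
        out.append((r + r.T) / 2.0)
    return out


def _off_mass(mats: np.ndarray) -> float:
    d = mats.copy()
    idx = np.arange(d.shape[1])
    d[:, idx, idx] = 0.0
    return float((d**2).sum())


def joint_diagonalize(
    matrices: Sequence[np.ndarray],
    tolerance: float = 1e-8,
    max_sweeps: int = 100,
    return_info: bool = False,
):
    """Orthogonal joint approximate diagonalization by Givens sweeps.

    Finds orthogonal ``V`` minimizing the summed squared off-diagonal mass
    of ``{V^T R_j V}``.  Each sweep visits every index pair once; the sweep
    loop stops when the largest rotation sine in a sweep falls below
    ``tolerance``.

    With ``return_info=True`` also returns a dict with the off-diagonal
    mass before and after each sweep (non-increasing) and the sweep count.
    """
    mats = [np.asarray(r, dtype=float) for r in matrices]
    if not mats:
        raise InvalidInputError("need at least one matrix")
    m = mats[0].shape[0]
    for r in mats:
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise InvalidInputError("matrices must be square")
        if r.shape[0] != m:
            raise InvalidInputError("matrices must share one size")
    ms = np.stack(mats)  # (J, m, m)
    v = np.eye(m)
    off_history = [_off_mass(ms)]
    n_sweeps = 0
    for n_sweeps in range(1, max_sweeps + 1):
        biggest = 0.0
        for p in range(m - 1):
            for q in range(p + 1, m):
                h_on = ms[:, p, p] - ms[:, q, q]
                h_off = ms[:, p, q] + ms[:, q, p]
                g_pp = float(h_on @ h_on)
                g_po = float(h_on @ h_off)
                g_oo = float(h_off @ h_off)
                # principal eigenvector of [[g_pp, g_po], [g_po, g_oo]]
                diff = g_pp - g_oo
                root = np.hypot(diff, 2.0 * g_po)
                ex = diff + root
                ey = 2.0 * g_po
                norm = np.hypot(ex, ey)
                if norm == 0.0:
                    continue
                ex, ey = ex / norm, ey / norm
                if ex < 0.0:
                    ex, ey = -ex, -ey
                theta = 0.5 * np.arctan2(ey, ex + np.hypot(ex, ey))
                c, s = np.cos(theta), np.sin(theta)
                if abs(s) <= tolerance:
                    continue
                biggest = max(biggest, abs(s))
                rot = np.array([[c, -s], [s, c]])
                ms[:, [p, q], :] = np.einsum("ab,jbt->jat", rot.T, ms[:, [p, q], :])
                ms[:, :, [p, q]] = np.einsum("jtb,ba->jta", ms[:, :, [p, q]], rot)
                v[:, [p, q]] = v[:, [p, q]] @ rot
        off_history.append(_off_mass(ms))
        if biggest <= tolerance:
            break
    if return_info:
        return v, {"off_mass": off_history, "n_sweeps": n_sweeps}
    return v


def sobi_separate(
    data: MultichannelData, cfg: SobiConfig | None = None
) -> SobiResult:
    """Run the full separation: whiten, estimate lagged covariances,
    jointly diagonalize, and back out mixing matrix and sources."""
    if cfg is None:
        cfg = SobiConfig()
    lags = cfg.lags if cfg.lags is not None else default_lags(data.n_samples)
    for tau in lags:
        if tau >= data.n_samples:
            raise InvalidConfigError(f"lag {tau} >= record length {data.n_samples}")
    q, z = whiten(data, ridge=cfg.ridge)
    covs = lagged_covariances(z, lags)
    v, info = joint_diagonalize(
        covs, tolerance=cfg.jd_tolerance, max_sweeps=cfg.max_sweeps, return_info=True
    )
    means = data.channels.mean(axis=1)
    sources = v.T @ z.channels
    mixing = np.linalg.inv(q) @ v
    return SobiResult(
        whitening=q,
        rotation=v,
        mixing=mixing,
        sources=sources,
        channel_means=means,
        fs=data.fs,
        n_sweeps=info["n_sweeps"],
    )
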