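"""Fuzzy entropy: a similarity-based complexity measure.

``FE = ln(phi_m) - ln(phi_{m+1})`` where ``phi_d`` is the mean pairwise
similarity of baseline-removed length-``d`` embedding vectors under the
exponential membership function ``exp(-(dist/r)^n)`` with Chebyshev
distance.  More irregular sequences score higher.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist

from .errors import InvalidConfigError, InvalidInputError

__all__ = ["FeConfig", "fuzzy_entropy"]


@dataclass(frozen=True)
class FeConfig:
    """Fuzzy-entropy parameters.

    ``r`` is the similarity tolerance; with ``r_relative=True`` (default)
    it is interpreted as a multiple of the sequence standard deviation,
    which makes the measure amplitude-scale invariant.
    """

    m: int = 2
    n_grad: float = 2.0
    r: float = 0.2
    r_relative: bool = True

    def __post_init__(self) -> None:
        if not (isinstance(self.m, (int, np.integer)) and self.m >= 1):
            raise InvalidConfigError("embedding dimension m must be an integer >= 1")
        if not self.n_grad > 0:
            raise InvalidConfigError("membership gradient must be positive")
        if not self.r > 0:
            raise InvalidConfigError("similarity tolerance must be positive")


def _phi(x: np.ndarray, dim: int, n_vec: int, r: float, n_grad: float) -> float:
    emb = sliding_window_view(x, dim)[:n_vec].astype(float)
    emb = emb - emb.mean(axis=1, keepdims=True)
    dists = cdist(emb, emb, metric="chebyshev")
    sim = np.exp(-((dists / r) ** n_grad))
    np.fill_diagonal(sim, 0.0)
    return float(sim.sum() / (n_vec * (n_vec - 1)))


def fuzzy_entropy(x, cfg: FeConfig | None = None) -> float:
    """Fuzzy entropy of a 1-D sequence.

    Both embedding levels use the same number of vectors (``len(x) - m``)
    so the two similarity averages are comparable; self-pairs are excluded.
    A zero-variance sequence returns 0 by the limit convention (all
    distances vanish, all similarities are 1).
    """
    if cfg is None:
        cfg = FeConfig()
    arr = np.asarray(getattr(x, "samples", x), dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError("sequence must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("sequence contains non-finite values")
    n = arr.size
    if n < cfg.m + 2:
        raise InvalidInputError(
            f"sequence of length {n} too short for embedding dimension {cfg.m}"
        )
    sd = float(arr.std())
    if sd == 0.0:
        return 0.0
    r = cfg.r * sd if cfg.r_relative else cfg.r
    n_vec = n - cfg.m
    phi_m = _phi(arr, cfg.m, n_vec, r, cfg.n_grad)
    phi_m1 = _phi(arr, cfg.m + 1, n_vec, r, cfg.n_grad)
    if phi_m <= 0.0 or phi_m1 <= 0.0:
        # similarities can underflow to exactly 0 for very spread-out data
        raise InvalidInputError("similarity average underflowed to zero")
    return float(np.log(phi_m) - np.log(phi_m1))
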