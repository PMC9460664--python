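"""Automatic selection of the VMD mode count K.

Decompose with each candidate K in a range, pair the center frequencies of
the K- and (K+1)-mode decompositions by ascending-frequency order, and form
the judgment accuracy ``eps_{K,a} = w_{K,a} / w_{K+1,a}``.  An entry is an
*invalid center frequency* when the ratio is ``<= theta1`` or ``>= theta2``
(defaults 1 and 1.2); the selected K is the smallest candidate whose row
contains any invalid entry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .signal import Signal
from .vmd import ModeSet, VmdConfig, vmd_decompose

__all__ = [
    "KSelectionTrace",
    "judgment_accuracy",
    "is_invalid",
    "select_from_accuracy_table",
    "select_k",
]

THETA1_DEFAULT = 1.0
THETA2_DEFAULT = 1.2
K_RANGE_DEFAULT = (2, 10)


def judgment_accuracy(freq_k: float, freq_k_plus_1: float) -> float:
    """Ratio of same-order center frequencies from consecutive mode counts."""
    if not freq_k > 0:
        raise InvalidInputError(f"numerator center frequency must be > 0, got {freq_k}")
    if not freq_k_plus_1 > 0:
        raise InvalidInputError(
            f"denominator center frequency must be > 0, got {freq_k_plus_1}"
        )
    return freq_k / freq_k_plus_1


def is_invalid(
    accuracy: float, theta1: float = THETA1_DEFAULT, theta2: float = THETA2_DEFAULT
) -> bool:
    """Whether a judgment accuracy marks an invalid center frequency.

    Both comparisons are inclusive: ``accuracy >= theta2 or accuracy <= theta1``.
    """
    if not accuracy > 0:
        raise InvalidInputError("accuracy must be positive")
    return accuracy >= theta2 or accuracy <= theta1


def select_from_accuracy_table(
    accuracy_rows: dict[int, list[float]],
    theta1: float = THETA1_DEFAULT,
    theta2: float = THETA2_DEFAULT,
) -> tuple[int | None, dict[int, list[bool]]]:
    """Apply the invalid-entry rule to a pre-computed accuracy table.

    ``accuracy_rows`` maps each candidate K (ascending) to its list of K
    judgment accuracies.  Returns ``(selected_k, flags)`` where flags mirror
    the table; ``selected_k`` is ``None`` when no row triggers.
    """
    flags: dict[int, list[bool]] = {}
    selected: int | None = None
    for k in sorted(accuracy_rows):
        row_flags = [is_invalid(a, theta1, theta2) for a in accuracy_rows[k]]
        flags[k] = row_flags
        if selected is None and any(row_flags):
            selected = k
    return selected, flags


@dataclass(frozen=True)
class KSelectionTrace:
    """Full record of a selection run.

    ``center_freq_table[K]`` holds the K ascending normalized center
    frequencies; ``accuracy_table[K]`` the K ratios against the (K+1)-mode
    run (so its keys stop one short of the top of ``k_range``).
    ``selected_k`` is ``None`` when no row triggered; ``fallback_k`` then
    carries ``max(k_range)`` as an advisory.
    """

    k_range: tuple[int, int]
    center_freq_table: dict[int, list[float]]
    accuracy_table: dict[int, list[float]]
    invalid_flags: dict[int, list[bool]]
    selected_k: int | None
    fallback_k: int | None = None
    mode_sets: dict[int, ModeSet] | None = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "k_range": list(self.k_range),
            "center_freq_table": {str(k): v for k, v in self.center_freq_table.items()},
            "accuracy_table": {str(k): v for k, v in self.accuracy_table.items()},
            "invalid_flags": {str(k): v for k, v in self.invalid_flags.items()},
            "selected_k": self.selected_k,
            "fallback_k": self.fallback_k,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def format_table(self) -> str:
        """Human-readable accuracy table with invalid entries starred."""
        lines = ["K   judgment accuracies (* = invalid)"]
        for k in sorted(self.accuracy_table):
            cells = [
                f"{a:.4f}{'*' if bad else ' '}"
                for a, bad in zip(self.accuracy_table[k], self.invalid_flags[k])
            ]
            lines.append(f"{k:<3d} " + "  ".join(cells))
        sel = self.selected_k if self.selected_k is not None else (
            f"none (fallback {self.fallback_k})"
        )
        lines.append(f"selected K = {sel}")
        return "\n".join(lines)


def select_k(
    signal: Signal,
    base_cfg: VmdConfig | None = None,
    k_range: tuple[int, int] = K_RANGE_DEFAULT,
    theta1: float = THETA1_DEFAULT,
    theta2: float = THETA2_DEFAULT,
    keep_mode_sets: bool = False,
) -> KSelectionTrace:
    """Run the decomposition across ``k_range`` and pick K.

    Decompositions run for every K in ``[k_min, k_max]``; accuracy rows
    exist for ``K in [k_min, k_max - 1]`` since each needs the (K+1)-run.
    Deterministic: identical signal + config reproduce the identical trace.
    """
    if base_cfg is None:
        base_cfg = VmdConfig()
    k_min, k_max = int(k_range[0]), int(k_range[1])
    if k_min < 1 or k_max < k_min:
        raise InvalidInputError(f"bad k_range {k_range}")

    mode_sets: dict[int, ModeSet] = {}
    cf_table: dict[int, list[float]] = {}
    for k in range(k_min, k_max + 1):
        ms = vmd_decompose(signal, base_cfg.with_k(k))
        mode_sets[k] = ms
        cf_table[k] = [float(w) for w in ms.center_freqs]

    acc_table: dict[int, list[float]] = {}
    for k in range(k_min, k_max):
        acc_table[k] = [
            judgment_accuracy(cf_table[k][a], cf_table[k + 1][a]) for a in range(k)
        ]

    selected, flags = select_from_accuracy_table(acc_table, theta1, theta2)
    return KSelectionTrace(
        k_range=(k_min, k_max),
        center_freq_table=cf_table,
        accuracy_table=acc_table,
        invalid_flags=flags,
        selected_k=selected,
        fallback_k=None if selected is not None else k_max,
        mode_sets=mode_sets if keep_mode_sets else None,
    )
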