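"""Cliff's delta effect sizes: unpaired dominance and paired sign-mean.

The unpaired statistic is the mean sign over the full difference matrix
``d[i, j] = y[j] - x[i]``; the paired variant is the mean sign of the
within-subject differences only, so its value always lies on the grid
``k / n`` for integer ``k``. Ties contribute zero in both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EffectSize", "cliffs_delta", "paired_cliffs_delta", "interpret_delta"]

#: Magnitude anchors (negligible below the first midpoint, then
#: nearest-anchor among small ~0.2, medium ~0.5, large ~0.8).
DEFAULT_THRESHOLDS = (0.11, 0.35, 0.65)
_LABELS = ("negligible", "small", "medium", "large")


@dataclass(frozen=True)
class EffectSize:
    """A Cliff's delta value with its kind, sample sizes and label."""

    delta: float
    kind: str  # "unpaired" | "paired"
    n_x: int
    n_y: int
    label: str

    def __post_init__(self) -> None:
        if not -1.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must lie in [-1, 1], got {self.delta}")
        if self.kind not in ("unpaired", "paired"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "paired" and self.n_x != self.n_y:
            raise ValueError("paired effect sizes require equal sample sizes")


def interpret_delta(delta: float, thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS) -> str:
    """Magnitude label for a delta via nearest-anchor boundaries on ``|delta|``."""
    if abs(delta) > 1:
        raise ValueError(f"|delta| cannot exceed 1, got {delta}")
    magnitude = abs(delta)
    for cut, label in zip(thresholds, _LABELS[:-1]):
        if magnitude < cut:
            return label
    return _LABELS[-1]


def cliffs_delta(x, y) -> EffectSize:
    """Unpaired Cliff's delta of sample ``y`` relative to sample ``x``.

    ``delta = sum_ij sign(y_j - x_i) / (n_x * n_y)``; positive values mean
    ``y`` tends to exceed ``x``. Computed via rank counts in
    O((n_x + n_y) log(n_x + n_y)) rather than the explicit matrix.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("cliffs_delta requires non-empty samples")
    # For each y_j: (#x < y_j) - (#x > y_j), via sorted-x binary search.
    xs = np.sort(x)
    n_less = np.searchsorted(xs, y, side="left")
    n_greater = x.size - np.searchsorted(xs, y, side="right")
    total = int((n_less - n_greater).sum())
    delta = total / (x.size * y.size)
    return EffectSize(delta=delta, kind="unpaired", n_x=int(x.size), n_y=int(y.size),
                      label=interpret_delta(delta))


def paired_cliffs_delta(x1, x2) -> EffectSize:
    """Paired Cliff's delta: mean sign of within-subject change ``x2 - x1``.

    Positive values indicate an increase at the second visit. Zero
    differences count as zero, so ``delta * n`` is always an integer.
    """
    x1 = np.asarray(x1, dtype=np.float64).ravel()
    x2 = np.asarray(x2, dtype=np.float64).ravel()
    if x1.size != x2.size:
        raise ValueError(f"paired samples differ in length: {x1.size} vs {x2.size}")
    if x1.size == 0:
        raise ValueError("paired_cliffs_delta requires at least one pair")
    delta = float(np.sign(x2 - x1).mean())
    return EffectSize(delta=delta, kind="paired", n_x=int(x1.size), n_y=int(x2.size),
                      label=interpret_delta(delta))
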