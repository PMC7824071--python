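"""Per-rater bias indicators and heterogeneity attribution.

The extended plot collapses the raters of each subject into one point, so
two pieces of per-rater information are restored separately: a tick mark per
rater at the magnitude of its mean deviation from the subject means (bias),
and a per-rater count of the subjects for which that rater deviates most
(variance heterogeneity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RatingsMatrix, max_dev_index

__all__ = ["BiasIndicators", "bias_indicators", "heterogeneity_attribution"]


@dataclass(frozen=True)
class BiasIndicators:
    """Bias tick-mark values ``B_j`` per rater.

    ``values[j] = | mean_i(x_ij - x_bar_i) |`` -- the absolute value of the
    mean signed deviation of rater ``j`` from the subject means.  Under pure
    noise each ``B_j`` converges to 0, so a persistently elevated tick mark
    isolates systematic rater bias.  The ``signed`` deviations (which sum to
    zero across raters exactly) are kept for reporting direction.
    """

    rater_ids: tuple[str, ...]
    values: np.ndarray
    signed: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        signed = np.asarray(self.signed, dtype=float)
        if values.shape != (len(self.rater_ids),) or signed.shape != values.shape:
            raise ValueError("one bias value per rater is required")
        if np.any(values < 0):
            raise ValueError("bias indicators are magnitudes and cannot be negative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "signed", signed)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.rater_ids, map(float, self.values)))


def bias_indicators(ratings: RatingsMatrix) -> BiasIndicators:
    """Bias indicator ``B_j`` for each rater (tick marks on the SD axis)."""
    dev = ratings.values - ratings.values.mean(axis=1, keepdims=True)
    signed = dev.mean(axis=0)
    return BiasIndicators(
        rater_ids=ratings.rater_ids,
        values=np.abs(signed),
        signed=signed,
    )


def heterogeneity_attribution(ratings: RatingsMatrix) -> dict[str, int]:
    """Count, per rater, the subjects for which it deviates most from the mean.

    Ties go to the first rater in column order (so for ``m = 2``, where both
    raters always deviate equally in magnitude, all counts fall on the first
    rater).  Counts sum to ``n``; a rater that dominates the counts has a
    larger measurement-error variance than the rest.
    """
    dev = np.abs(ratings.values - ratings.values.mean(axis=1, keepdims=True))
    max_idx = max_dev_index(dev)
    counts = np.bincount(max_idx, minlength=ratings.m)
    return dict(zip(ratings.rater_ids, map(int, counts)))
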