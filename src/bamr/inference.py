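"""Bootstrap confidence interval for the extended limit of agreement.

Subjects are the independent units of the model, so resampling draws whole
subject rows with replacement; the limit is recomputed on each resample and
a bias-corrected and accelerated (BCa) interval is read off the resampled
distribution.  The acceleration constant comes from the leave-one-subject-out
jackknife.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import (
    LimitOfAgreement,
    RatingsMatrix,
    expected_sd_ratio,
    loa_factor,
    subject_means_sds,
)

__all__ = ["BootstrapSpec", "bootstrap_loa_ci"]


@dataclass(frozen=True)
class BootstrapSpec:
    """Settings for the BCa bootstrap of the limit of agreement.

    ``level`` is the confidence level of the interval (the limit itself keeps
    its own quantile level).  A fixed ``seed`` makes the interval
    bit-reproducible.
    """

    n_boot: int = 1000
    level: float = 0.95
    seed: int | None = None
    method: str = "bca"

    def __post_init__(self) -> None:
        if self.n_boot < 2:
            raise ValueError(f"n_boot must be >= 2, got {self.n_boot}")
        if not 0.0 < self.level < 1.0:
            raise ValueError(f"level must be in (0, 1), got {self.level}")
        if self.method != "bca":
            raise ValueError(f"only the 'bca' method is supported, got {self.method!r}")


def _loa_from_sds(sds: np.ndarray, factor: float, c4: float) -> np.ndarray:
    """Limit of agreement from per-subject SDs along the last axis."""
    return factor * np.mean(sds, axis=-1) / c4


def bootstrap_loa_ci(
    ratings: RatingsMatrix,
    spec: BootstrapSpec | None = None,
    loa_level: float = 0.95,
) -> LimitOfAgreement:
    """Extended LOA with a BCa bootstrap confidence interval attached.

    The statistic is a smooth function of the per-subject SDs alone, so
    resampling subject rows is equivalent to resampling the SD vector.
    Degenerate situations are handled explicitly: if every resampled limit is
    identical the interval collapses to the point estimate, and if the
    bias-correction quantile is degenerate (all resamples on one side of the
    estimate, where the BCa z0 is infinite) plain percentile bounds are
    returned; both cases emit a warning.
    """
    spec = spec or BootstrapSpec()
    if ratings.n < 3:
        raise ValueError(
            f"the BCa interval needs at least 3 subjects for the jackknife, got n={ratings.n}"
        )
    n, m = ratings.n, ratings.m
    factor = loa_factor(m, loa_level)
    c4 = expected_sd_ratio(m)
    _, sds = subject_means_sds(ratings.values)
    estimate = float(_loa_from_sds(sds, factor, c4))

    rng = np.random.default_rng(spec.seed)
    idx = rng.integers(0, n, size=(spec.n_boot, n))
    boot = _loa_from_sds(sds[idx], factor, c4)

    if np.ptp(boot) == 0.0:
        warnings.warn(
            "all bootstrap resamples give the same limit; the confidence interval "
            "collapses to the point estimate",
            UserWarning,
            stacklevel=2,
        )
        lo = hi = estimate
    else:
        alpha = 1.0 - spec.level
        frac_below = np.mean(boot < estimate)
        if frac_below == 0.0 or frac_below == 1.0:
            warnings.warn(
                "degenerate bias correction (all resampled limits on one side of the "
                "estimate); falling back to percentile bounds",
                UserWarning,
                stacklevel=2,
            )
            a1, a2 = alpha / 2, 1 - alpha / 2
        else:
            z0 = stats.norm.ppf(frac_below)
            # leave-one-subject-out jackknife; the statistic is linear in the
            # subject SDs so the jackknife means have a closed form
            sum_s = sds.sum()
            jack = factor * (sum_s - sds) / (n - 1) / c4
            dev = jack.mean() - jack
            denom = np.sum(dev**2) ** 1.5
            accel = 0.0 if denom == 0.0 else float(np.sum(dev**3) / (6.0 * denom))
            z_lo, z_hi = stats.norm.ppf([alpha / 2, 1 - alpha / 2])
            a1 = float(stats.norm.cdf(z0 + (z0 + z_lo) / (1 - accel * (z0 + z_lo))))
            a2 = float(stats.norm.cdf(z0 + (z0 + z_hi) / (1 - accel * (z0 + z_hi))))
        lo, hi = (float(q) for q in np.quantile(boot, [a1, a2]))

    return LimitOfAgreement(
        estimate=estimate,
        m=m,
        n=n,
        mean_sd=float(sds.mean()),
        method="extended_chi",
        level=loa_level,
        ci_lower=min(lo, estimate),
        ci_upper=max(hi, estimate),
        bootstrap=spec,
    )
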