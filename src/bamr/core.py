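"""Core types and closed-form limits of agreement.

The extended Bland-Altman plot summarises an ``n`` subjects x ``m`` raters
table of continuous measurements by one point per subject: the subject mean
``x_bar_i`` on the x-axis and the intra-subject standard deviation ``s_i``
(divisor ``m - 1``) on the y-axis.  Under the homoscedastic normal model

    X_ij = mu_i + gamma_j + eps_ij,    eps_ij ~ N(0, sigma^2) iid,

and in the absence of rater bias, ``s_i * sqrt(m - 1) / sigma`` follows a
chi distribution with ``m - 1`` degrees of freedom, which yields a one-sided
95% limit of agreement for the intra-subject SD:

    L = chi_{0.95, m-1} / sqrt(m - 1) * sigma_hat,

where ``sigma_hat`` estimates the measurement-error SD from the average
intra-subject SD (see :func:`extended_loa`).  For ``m = 2`` the classical
two-rater Bland-Altman quantities are provided as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import special, stats

__all__ = [
    "RatingsMatrix",
    "SubjectSummary",
    "LimitOfAgreement",
    "ClassicalBAResult",
    "subject_stats",
    "loa_factor",
    "expected_sd_ratio",
    "extended_loa",
    "classical_ba",
]


def _default_labels(prefix: str, count: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{i + 1}" for i in range(count))


@dataclass(frozen=True)
class RatingsMatrix:
    """A complete n x m table of continuous ratings.

    Parameters
    ----------
    values
        Real measurements, shape ``(n, m)``; every cell present and finite.
    subject_ids
        ``n`` unique subject labels (defaults to ``S1..Sn``).
    rater_ids
        ``m`` unique rater labels (defaults to ``R1..Rm``).
    """

    values: np.ndarray
    subject_ids: tuple[str, ...] = ()
    rater_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"ratings must be a 2-D array, got shape {values.shape}")
        n, m = values.shape
        if n < 2:
            raise ValueError(f"at least 2 subjects are required, got n={n}")
        if m < 2:
            raise ValueError(f"at least 2 raters are required, got m={m}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))
            raise ValueError(
                "ratings must be complete and finite; "
                f"non-finite cells at (subject, rater) indices {bad[:5].tolist()}"
            )
        subject_ids = tuple(str(s) for s in self.subject_ids) or _default_labels("S", n)
        rater_ids = tuple(str(r) for r in self.rater_ids) or _default_labels("R", m)
        if len(subject_ids) != n:
            raise ValueError(f"{len(subject_ids)} subject labels for {n} rows")
        if len(rater_ids) != m:
            raise ValueError(f"{len(rater_ids)} rater labels for {m} columns")
        if len(set(subject_ids)) != n:
            raise ValueError("subject labels must be unique")
        if len(set(rater_ids)) != m:
            raise ValueError("rater labels must be unique")
        values = values.copy()
        values.flags.writeable = False
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "subject_ids", subject_ids)
        object.__setattr__(self, "rater_ids", rater_ids)

    @property
    def n(self) -> int:
        """Number of subjects."""
        return self.values.shape[0]

    @property
    def m(self) -> int:
        """Number of raters."""
        return self.values.shape[1]

    def to_frame(self):
        """Wide pandas DataFrame: one row per subject, one column per rater."""
        import pandas as pd

        return pd.DataFrame(
            np.asarray(self.values),
            index=pd.Index(self.subject_ids, name="subject"),
            columns=list(self.rater_ids),
        )


@dataclass(frozen=True)
class SubjectSummary:
    """Per-subject mean, intra-subject SD, and the most-deviating rater."""

    subject_id: str
    mean: float
    sd: float
    max_dev_rater: str


@dataclass(frozen=True)
class LimitOfAgreement:
    """A one-sided limit of agreement for the intra-subject SD.

    ``estimate = loa_factor(m, level) * mean_sd / expected_sd_ratio(m)`` for
    the chi-based method; ``mean_sd`` is the plain average intra-subject SD
    and the ``expected_sd_ratio`` rescaling makes the plugged-in scale a
    consistent estimator of the error SD.  ``ci_lower``/``ci_upper`` are
    attached by the bootstrap in :mod:`bamr.inference`.
    """

    estimate: float
    m: int
    n: int
    mean_sd: float
    method: str = "extended_chi"
    level: float = 0.95
    ci_lower: float | None = None
    ci_upper: float | None = None
    bootstrap: Any = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.estimate < 0:
            raise ValueError("limit of agreement cannot be negative")
        if self.method not in ("extended_chi", "classical_t"):
            raise ValueError(f"unknown method {self.method!r}")
        if (self.ci_lower is None) != (self.ci_upper is None):
            raise ValueError("confidence bounds must be attached together")
        if self.ci_lower is not None:
            if not self.ci_lower <= self.estimate <= self.ci_upper:
                raise ValueError(
                    f"confidence interval [{self.ci_lower}, {self.ci_upper}] "
                    f"does not bracket the estimate {self.estimate}"
                )

    @property
    def has_ci(self) -> bool:
        return self.ci_lower is not None


@dataclass(frozen=True)
class ClassicalBAResult:
    """Classical two-rater Bland-Altman summary (difference scale)."""

    pair_means: np.ndarray
    differences: np.ndarray
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    level: float = 0.95


def subject_means_sds(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vector of subject means and intra-subject SDs (divisor ``m - 1``)."""
    values = np.asarray(values, dtype=float)
    return values.mean(axis=1), values.std(axis=1, ddof=1)


def max_dev_index(abs_dev: np.ndarray) -> np.ndarray:
    """First rater index attaining the per-subject maximum absolute deviation.

    Deviations within one part in 1e12 of the row maximum count as tied, so
    exact ties (for ``m = 2`` both raters always deviate equally) resolve to
    the first column despite floating-point rounding of the subject mean.
    """
    mx = abs_dev.max(axis=1, keepdims=True)
    return np.argmax(abs_dev >= mx * (1.0 - 1e-12), axis=1)


def subject_stats(ratings: RatingsMatrix) -> list[SubjectSummary]:
    """Per-subject mean, SD and the rater with the largest absolute deviation.

    Ties in the deviation are broken toward the first rater in column order,
    so the attribution is deterministic and order-stable.
    """
    means, sds = subject_means_sds(ratings.values)
    dev = np.abs(ratings.values - means[:, None])
    max_idx = max_dev_index(dev)
    return [
        SubjectSummary(
            subject_id=ratings.subject_ids[i],
            mean=float(means[i]),
            sd=float(sds[i]),
            max_dev_rater=ratings.rater_ids[max_idx[i]],
        )
        for i in range(ratings.n)
    ]


def loa_factor(m: int, level: float = 0.95) -> float:
    """Chi-distribution multiplier ``chi_{level, m-1} / sqrt(m - 1)``.

    This is the factor by which a consistent estimate of the error SD is
    multiplied to obtain the limit of agreement for the intra-subject SD.
    It decreases from 1.959964 at ``m = 2`` toward 1 as ``m`` grows.
    """
    if int(m) != m or m < 2:
        raise ValueError(f"m must be an integer >= 2, got {m!r}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    df = int(m) - 1
    return float(np.sqrt(stats.chi2.ppf(level, df) / df))


def expected_sd_ratio(m: int) -> float:
    """``E[s_i] / sigma`` for the SD of ``m`` iid normal ratings.

    Closed form ``sqrt(2/(m-1)) * Gamma(m/2) / Gamma((m-1)/2)`` (the mean of
    a chi_{m-1} variable divided by ``sqrt(m-1)``); the classical ``c4``
    unbiasing constant of the sample SD.
    """
    if int(m) != m or m < 2:
        raise ValueError(f"m must be an integer >= 2, got {m!r}")
    m = int(m)
    df = m - 1
    return float(
        np.exp(0.5 * np.log(2.0 / df) + special.gammaln(m / 2) - special.gammaln(df / 2))
    )


def extended_loa(ratings: RatingsMatrix, level: float = 0.95) -> LimitOfAgreement:
    """Chi-based limit of agreement for the extended Bland-Altman plot.

    The error-SD scale is estimated by the average intra-subject SD rescaled
    by its normal-theory expectation, ``sigma_hat = mean(s_i) /
    expected_sd_ratio(m)``; without this calibration the plain average SD
    underestimates sigma (by ~20% at ``m = 2``) and the limit would fall far
    short of the nominal level.  The returned limit carries no confidence
    interval; use :func:`bamr.inference.bootstrap_loa_ci` for one.
    """
    _, sds = subject_means_sds(ratings.values)
    mean_sd = float(sds.mean())
    if mean_sd == 0.0:
        warnings.warn(
            "all raters agree exactly on every subject; the limit of agreement is 0",
            UserWarning,
            stacklevel=2,
        )
    estimate = loa_factor(ratings.m, level) * mean_sd / expected_sd_ratio(ratings.m)
    return LimitOfAgreement(
        estimate=estimate,
        m=ratings.m,
        n=ratings.n,
        mean_sd=mean_sd,
        method="extended_chi",
        level=level,
    )


def classical_ba(ratings: RatingsMatrix, level: float = 0.95) -> ClassicalBAResult:
    """Classical Bland-Altman quantities for exactly two raters.

    Differences are oriented first column minus second column; reorder the
    rater columns to flip the sign convention.  The limits use the exact
    small-sample factor ``t_{(1+level)/2, n-1} * sqrt(1 + 1/n)`` (a prediction
    interval for one new difference) rather than the large-n constant 1.96.
    """
    if ratings.m != 2:
        raise ValueError(f"classical Bland-Altman requires exactly 2 raters, got m={ratings.m}")
    d = ratings.values[:, 0] - ratings.values[:, 1]
    n = ratings.n
    bias = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    half = float(stats.t.ppf((1 + level) / 2, n - 1) * np.sqrt(1 + 1 / n) * sd_diff)
    return ClassicalBAResult(
        pair_means=ratings.values.mean(axis=1),
        differences=d,
        bias=bias,
        sd_diff=sd_diff,
        loa_lower=bias - half,
        loa_upper=bias + half,
        level=level,
    )
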