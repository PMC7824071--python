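"""Synthetic rating scenarios for demos, fixtures, and property tests.

Four named scenarios cover the situations an agreement study needs to
recognise:

``homogeneous``
    The bias-free homoscedastic model ``X_ij = mu_i + eps_ij`` with a common
    error SD ``sigma`` (default 2) -- the setting in which the chi-based
    limit of agreement is exact for large ``n``.
``rater_bias``
    One rater (the second, by default) measures systematically one error SD
    above the true value (``gamma_2 = sigma``); its bias tick mark separates
    from the rest.
``rater_heteroscedastic``
    One rater (the second) has a much larger error SD (40 vs 2 by default);
    that rater dominates the max-deviation attribution counts.
``funnel``
    The error SD grows with the subject's true value,
    ``SD(eps_ij) = sigma + funnel_slope * mu_i`` -- the classic funnel shape
    of variance increasing with magnitude.  The affine form is the simplest
    monotone choice.

Subject true values are drawn uniformly on ``mu_range`` so plots have spread
on the x-axis; the model itself imposes nothing on them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RatingsMatrix

__all__ = ["ScenarioSpec", "scenario", "generate", "FIXTURE_SPECS", "fixture"]

SCENARIO_NAMES = ("homogeneous", "rater_bias", "rater_heteroscedastic", "funnel")


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of one synthetic scenario (name + model parameters)."""

    name: str
    n: int
    m: int
    sigma: float = 2.0
    rater_bias_values: tuple[float, ...] | None = None
    rater_sigma_overrides: tuple[float, ...] | None = None
    funnel_slope: float = 0.0
    mu_range: tuple[float, float] = (10.0, 50.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.name!r}; choose from {SCENARIO_NAMES}")
        if self.n < 2 or self.m < 2:
            raise ValueError(f"need n >= 2 and m >= 2, got n={self.n}, m={self.m}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        for name, tup in (
            ("rater_bias_values", self.rater_bias_values),
            ("rater_sigma_overrides", self.rater_sigma_overrides),
        ):
            if tup is not None and len(tup) != self.m:
                raise ValueError(f"{name} must have one entry per rater (m={self.m})")
        if self.rater_sigma_overrides is not None and any(
            s <= 0 for s in self.rater_sigma_overrides
        ):
            raise ValueError("per-rater SDs must be positive")
        if self.funnel_slope < 0:
            raise ValueError(f"funnel_slope must be >= 0, got {self.funnel_slope}")
        if self.mu_range[0] >= self.mu_range[1]:
            raise ValueError(f"empty mu_range {self.mu_range}")
        if self.name == "funnel":
            lo = self.sigma + self.funnel_slope * self.mu_range[0]
            if self.mu_range[0] <= 0 or lo <= 0:
                raise ValueError(
                    "funnel scenario needs positive true values and a positive error SD "
                    f"over the whole mu_range, got mu_range={self.mu_range}"
                )


def scenario(name: str, n: int, m: int, seed: int | None = None, sigma: float = 2.0,
             **overrides) -> ScenarioSpec:
    """Build a :class:`ScenarioSpec` with the scenario's standard settings.

    ``rater_bias`` sets ``gamma_2 = sigma`` and ``rater_heteroscedastic``
    sets the second rater's SD to 40 (others ``sigma``); ``funnel`` uses an
    SD slope of 0.1 per unit of true value.  Any field can be overridden.
    """
    defaults: dict = {}
    if name == "rater_bias":
        gamma = [0.0] * m
        gamma[1] = sigma
        defaults["rater_bias_values"] = tuple(gamma)
    elif name == "rater_heteroscedastic":
        sigmas = [sigma] * m
        sigmas[1] = 40.0
        defaults["rater_sigma_overrides"] = tuple(sigmas)
    elif name == "funnel":
        defaults["funnel_slope"] = 0.1
    defaults.update(overrides)
    return ScenarioSpec(name=name, n=n, m=m, sigma=sigma, seed=seed, **defaults)


def generate(spec: ScenarioSpec) -> RatingsMatrix:
    """Simulate one ratings table from a scenario; fixed seed, fixed output."""
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n, spec.m
    mu = rng.uniform(*spec.mu_range, size=n)
    gamma = np.zeros(m) if spec.rater_bias_values is None else np.asarray(spec.rater_bias_values)
    if spec.name == "funnel":
        sd = (spec.sigma + spec.funnel_slope * mu)[:, None]
    elif spec.rater_sigma_overrides is not None:
        sd = np.asarray(spec.rater_sigma_overrides)[None, :]
    else:
        sd = spec.sigma
    values = mu[:, None] + gamma[None, :] + sd * rng.standard_normal((n, m))
    return RatingsMatrix(values)


#: Frozen scenario fixtures (spec + seed) shared by the test suite and docs.
FIXTURE_SPECS: dict[str, ScenarioSpec] = {
    "homogeneous": scenario("homogeneous", n=50, m=3, seed=101),
    "rater_bias": scenario("rater_bias", n=100, m=3, seed=102),
    "rater_heteroscedastic": scenario("rater_heteroscedastic", n=100, m=3, seed=103),
    "funnel": scenario("funnel", n=200, m=3, seed=104),
}


def fixture(name: str) -> RatingsMatrix:
    """Generate one of the frozen named fixtures."""
    try:
        spec = FIXTURE_SPECS[name]
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURE_SPECS)}") from None
    return generate(spec)
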