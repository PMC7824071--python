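"""Rendering of extended and classical Bland-Altman plots.

Figures are built on plain :class:`matplotlib.figure.Figure` objects (no
pyplot state), so plotting is side-effect-free and works headless.  Every
quantity drawn -- LOA height, confidence band bounds, bias tick positions --
is placed in the figure's data model under a stable ``gid`` so it can be
checked programmatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from matplotlib.figure import Figure

from .core import RatingsMatrix, classical_ba, extended_loa, subject_stats
from .diagnostics import bias_indicators
from .inference import BootstrapSpec, bootstrap_loa_ci

__all__ = ["PlotConfig", "extended_ba_plot", "classical_ba_plot"]

# Okabe-Ito palette: color-blind-safe categorical colors, cycled by rater index
_PALETTE = (
    "#0072B2", "#D55E00", "#009E73", "#CC79A7",
    "#E69F00", "#56B4E9", "#F0E442", "#000000",
)


@dataclass(frozen=True)
class PlotConfig:
    """Options for the extended Bland-Altman plot.

    ``rescale_sqrt2`` multiplies the SD axis by sqrt(2), putting it on the
    scale of a two-rater difference for comparison with a clinically
    relevant difference; off by default because the plain axis keeps its
    interpretation as a within-subject SD.
    """

    show_ci_band: bool = True
    rescale_sqrt2: bool = False
    color_by_max_dev: bool = True
    show_bias_ticks: bool = True
    level: float = 0.95
    output_format: str = "png"

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError(f"level must be in (0, 1), got {self.level}")
        if self.output_format not in ("png", "svg", "pdf"):
            raise ValueError(f"output_format must be png, svg or pdf, got {self.output_format!r}")


def _save(fig: Figure, path, config: PlotConfig) -> None:
    if path is not None:
        path = str(path)
        fmt = path.rsplit(".", 1)[-1].lower() if "." in path else config.output_format
        fig.savefig(path, format=fmt, dpi=150, bbox_inches="tight")


def extended_ba_plot(
    ratings: RatingsMatrix,
    config: PlotConfig | None = None,
    loa=None,
    bootstrap: BootstrapSpec | None = None,
    path=None,
) -> Figure:
    """Extended Bland-Altman plot: (subject mean, intra-subject SD) scatter.

    Draws the chi-based LOA as a horizontal line with (by default) a shaded
    bootstrap confidence band, right-axis tick marks at the per-rater bias
    indicators, and markers colored by the most-deviating rater.  A
    precomputed ``loa`` (e.g. from :func:`bamr.inference.bootstrap_loa_ci`)
    is honoured; otherwise the limit -- and, if the band is requested, its
    bootstrap CI -- is computed here.  ``path`` saves the figure.
    """
    config = config or PlotConfig()
    if loa is None:
        if config.show_ci_band:
            loa = bootstrap_loa_ci(ratings, bootstrap, loa_level=config.level)
        else:
            loa = extended_loa(ratings, level=config.level)
    if not math.isclose(loa.level, config.level):
        raise ValueError(
            f"LOA level {loa.level} does not match the plot config level {config.level}"
        )
    if config.show_ci_band and not loa.has_ci:
        raise ValueError("show_ci_band requires a limit of agreement with a confidence interval")

    scale = math.sqrt(2) if config.rescale_sqrt2 else 1.0
    stats_ = subject_stats(ratings)
    means = np.array([s.mean for s in stats_])
    sds = np.array([s.sd for s in stats_]) * scale
    max_dev = np.array([s.max_dev_rater for s in stats_])

    fig = Figure(figsize=(7, 5))
    ax = fig.add_subplot()

    if config.color_by_max_dev:
        for j, rater in enumerate(ratings.rater_ids):
            sel = max_dev == rater
            ax.scatter(
                means[sel], sds[sel],
                color=_PALETTE[j % len(_PALETTE)],
                label=f"max dev: {rater}", gid=f"points:{rater}",
                s=22, alpha=0.85, edgecolors="none",
            )
        ax.legend(loc="upper right", frameon=False, fontsize=8)
    else:
        ax.scatter(means, sds, color=_PALETTE[0], gid="points", s=22, alpha=0.85,
                   edgecolors="none")

    ax.axhline(loa.estimate * scale, color="0.2", linestyle="--", gid="loa-line",
               label=None)
    if config.show_ci_band:
        ax.axhspan(loa.ci_lower * scale, loa.ci_upper * scale, color="0.2",
                   alpha=0.18, gid="loa-ci-band")

    if config.show_bias_ticks:
        bias = bias_indicators(ratings)
        sec = ax.secondary_yaxis("right")
        sec.set_gid("bias-ticks")
        sec.set_yticks(list(bias.values * scale), labels=list(bias.rater_ids))
        sec.tick_params(axis="y", length=9, labelsize=8)
        sec.set_ylabel("rater bias $B_j$")

    ax.set_xlabel("subject mean")
    if config.rescale_sqrt2:
        ax.set_ylabel(r"$\sqrt{2}\,\times$ intra-subject SD (difference scale)")
    else:
        ax.set_ylabel("intra-subject SD")
    ax.set_title(f"Extended Bland-Altman plot (n={ratings.n}, m={ratings.m})")
    ax.set_ylim(bottom=0)  # an SD axis is one-sided

    _save(fig, path, config)
    return fig


def classical_ba_plot(
    ratings: RatingsMatrix,
    config: PlotConfig | None = None,
    path=None,
) -> Figure:
    """Classical two-rater Bland-Altman plot: (pair mean, difference).

    Scatter of the per-subject differences against the pair means with the
    bias line and the upper/lower limits of agreement.  No confidence lines
    are drawn on the classical plot.
    """
    config = config or PlotConfig()
    result = classical_ba(ratings, level=config.level)

    fig = Figure(figsize=(7, 5))
    ax = fig.add_subplot()
    ax.scatter(result.pair_means, result.differences, color=_PALETTE[0], gid="points",
               s=22, alpha=0.85, edgecolors="none")
    ax.axhline(result.bias, color="0.2", gid="bias-line")
    ax.axhline(result.loa_upper, color="0.2", linestyle="--", gid="loa-upper-line")
    ax.axhline(result.loa_lower, color="0.2", linestyle="--", gid="loa-lower-line")
    ax.set_xlabel("pair mean")
    ax.set_ylabel(f"difference ({ratings.rater_ids[0]} $-$ {ratings.rater_ids[1]})")
    ax.set_title(f"Classical Bland-Altman plot (n={ratings.n})")

    _save(fig, path, config)
    return fig


def artist_by_gid(fig: Figure, gid: str):
    """Find the single artist with the given ``gid`` (for programmatic checks)."""
    found = [a for ax in fig.axes for a in ax.get_children() if a.get_gid() == gid]
    if len(found) != 1:
        raise LookupError(f"expected exactly one artist with gid {gid!r}, found {len(found)}")
    return found[0]
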