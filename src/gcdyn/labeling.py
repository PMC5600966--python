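"""Emulation of confetti/brainbow multicolor fate mapping.

In the experiments that motivate this package, germinal center B cells
stochastically recombine a multicolor reporter allele at an induced time
point, after the founding clones have already proliferated.  Each
recombined cell and all its descendants carry one of up to K heritable
fluorescent colors, and clonality is then read out as the fraction of the
labeled population occupied by the dominant color.  Because several clones
can adopt the same color (and some cells none), the dominant color fraction
is a biased proxy that overestimates dominance in very diverse populations.
This module applies that observation process to simulated populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulator import Population

__all__ = ["LabelingPlan", "ColorLabeling", "apply_labeling", "dominant_color_fraction"]


@dataclass(frozen=True)
class LabelingPlan:
    """When and how a simulated run is color-labeled.

    ``day`` is the absolute simulation day (default: start of competition —
    the mapping from experimental Tamoxifen timing to model time is a free
    choice); ``n_colors`` the number of distinguishable colors K;
    ``p_recombine`` the per-cell probability of adopting any color (not
    specified by the motivating experiments, hence a free parameter).
    """

    day: float | None = None
    n_colors: int = 10
    p_recombine: float = 1.0

    def __post_init__(self):
        if self.n_colors < 1:
            raise ValueError("n_colors must be >= 1")
        if not 0.0 <= self.p_recombine <= 1.0:
            raise ValueError("p_recombine must be in [0, 1]")


@dataclass
class ColorLabeling:
    """Outcome of one labeling event: per-cell colors (0 = unlabeled)."""

    time: float
    n_colors: int
    p_recombine: float
    colors: np.ndarray

    @property
    def n_labeled(self) -> int:
        return int((self.colors > 0).sum())


def apply_labeling(
    population: Population,
    n_colors: int = 10,
    p_recombine: float = 1.0,
    rng: np.random.Generator | None = None,
) -> ColorLabeling:
    """Label each live cell independently with one of ``n_colors`` colors.

    A cell recombines with probability ``p_recombine`` and then picks a
    color uniformly (real reporter alleles have non-uniform color
    frequencies, but none are specified here); otherwise it stays
    unlabeled.  The labels are attached to the population (``color`` array)
    so that subsequent simulation propagates them to descendants.
    """
    if population.size == 0:
        raise ValueError("cannot label an empty population")
    if not 0.0 <= p_recombine <= 1.0:
        raise ValueError("p_recombine must be in [0, 1]")
    if n_colors < 1:
        raise ValueError("n_colors must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    labeled = rng.random(population.size) < p_recombine
    colors = np.where(
        labeled, rng.integers(1, n_colors + 1, population.size), 0
    ).astype(np.int64)
    population.color = colors
    population.n_colors = n_colors
    return ColorLabeling(population.t, n_colors, p_recombine, colors)


def dominant_color_fraction(population: Population) -> float:
    """Largest single-color share of the labeled cells (NaN if none labeled).

    The experimental dominance readout: among labeled cells, the fraction
    carrying the most common color.  In a maximally diverse population this
    exceeds the true dominant-clone fraction in expectation, since multiple
    clones can share a color.
    """
    if population.color is None:
        raise ValueError("population carries no color labels")
    counts = np.bincount(population.color)
    labeled = counts[1:].sum()
    if labeled == 0:
        return float("nan")
    return float(counts[1:].max() / labeled)
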