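"""Fitness functions mapping channel-expression phenotypes to survival.

A fitness function maps a conductance phenotype (1D G_Na, 1D G_K, or a
2D pair) to a survival probability in [0, 1].  Discontinuities in
physiological performance (conduction failure, the Type 3 to Type 2
excitability transition) become step functions -- fitness cliffs -- whose
plateau value is exactly 1; graded performance (conduction velocity, action
potential duration, metabolic cost) becomes graded functions built by
rescaling curves tabulated from the cable model.

All functions are vectorized over numpy arrays and tolerate any real input
(phenotypes are clamped to zero before evaluation upstream; values outside
a tabulated range are clamped to the table edge).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FitnessFunction",
    "cliff",
    "band",
    "velocity_fitness",
    "velocity_minus_cost",
    "apd_fitness",
    "Region2D",
    "region_fitness_2d",
]


@dataclass(frozen=True)
class FitnessFunction:
    """Phenotype -> survival probability in [0, 1].

    ``domain`` is ``"g_na"``, ``"g_k"`` or ``"2d"``; ``label`` records which
    selection scenario the function encodes.  Calling with arrays returns an
    array clipped into [0, 1].
    """

    fn: Callable[..., np.ndarray] = field(repr=False)
    domain: str = "g_na"
    label: str = ""

    def __call__(self, *phenotypes) -> np.ndarray:
        args = [np.asarray(p, dtype=float) for p in phenotypes]
        return np.clip(self.fn(*args), 0.0, 1.0)

    def tabulate(self, *grids: Sequence[float]) -> pd.DataFrame:
        """(phenotype, fitness) table for inspection/serialization."""
        if self.domain == "2d":
            g1, g2 = (np.asarray(g, dtype=float) for g in grids)
            xx, yy = np.meshgrid(g1, g2, indexing="ij")
            return pd.DataFrame(
                {
                    "g_na": xx.ravel(),
                    "g_k": yy.ravel(),
                    "fitness": self(xx.ravel(), yy.ravel()),
                }
            )
        (g,) = grids
        g = np.asarray(g, dtype=float)
        return pd.DataFrame({self.domain: g, "fitness": self(g)})


def cliff(threshold: float, side: str = "above", domain: str = "g_na") -> FitnessFunction:
    """Step fitness: 1 on the surviving side of ``threshold``, else 0.

    Survival at exactly the threshold is inclusive; ``side`` names the
    surviving side ("above" or "below").
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if side not in ("above", "below"):
        raise ValueError("side must be 'above' or 'below'")
    if side == "above":
        fn = lambda g: (g >= threshold).astype(float)
    else:
        fn = lambda g: (g <= threshold).astype(float)
    return FitnessFunction(fn=fn, domain=domain, label=f"cliff_{side}_{threshold:g}")


def band(lo: float, hi: float, domain: str = "g_k") -> FitnessFunction:
    """Survival inside the closed interval [lo, hi] (two opposing cliffs)."""
    if not lo <= hi:
        raise ValueError("need lo <= hi")
    return FitnessFunction(
        fn=lambda g: ((g >= lo) & (g <= hi)).astype(float),
        domain=domain,
        label=f"band_{lo:g}_{hi:g}",
    )


def _interp_table(table: pd.DataFrame, column: str):
    x = np.asarray(table["conductance"], dtype=float)
    y = np.asarray(table[column], dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]

    def interp(g):
        return np.interp(g, x, y)  # clamps at the table edges

    return interp, x, y


def velocity_fitness(
    curve: pd.DataFrame,
    cliff_threshold: float,
    floor: float = 0.9,
    domain: str = "g_na",
) -> FitnessFunction:
    """Graded selection for conduction velocity above a conduction cliff.

    The tabulated velocity is affinely rescaled onto [floor, 1] between its
    value at the cliff and its maximum, composed with the conduction cliff
    (0 below it).  A high floor makes selection on velocity weak relative
    to the cliff, matching the narrow dynamic range of the scenario this
    encodes; the resulting function is monotone nondecreasing up to the
    velocity peak.
    """
    if not 0.0 <= floor < 1.0:
        raise ValueError("floor must lie in [0, 1)")
    interp, x, y = _interp_table(curve, "velocity_m_per_s")
    v_lo = float(interp(cliff_threshold))
    v_hi = float(np.max(y))
    if v_hi <= v_lo:
        raise ValueError("velocity curve must increase above the cliff")

    def fn(g):
        scaled = floor + (1.0 - floor) * (interp(g) - v_lo) / (v_hi - v_lo)
        return np.where(g >= cliff_threshold, np.clip(scaled, floor, 1.0), 0.0)

    return FitnessFunction(fn=fn, domain=domain, label="velocity_scaled")


def velocity_minus_cost(
    curve: pd.DataFrame,
    cost_slope: float,
    cliff_threshold: float,
    domain: str = "g_na",
) -> FitnessFunction:
    """Velocity benefit minus a linear metabolic cost of sodium conductance.

    ``cost_slope`` is in velocity units (m/s) per mS/cm^2, approximating the
    roughly linear growth of sodium flux per action potential with G_Na.
    The net benefit ``v(g) - cost_slope * g`` is renormalized onto [0, 1]
    over the tabulated range above the cliff, so the unique interior
    maximum has fitness exactly 1; below the cliff fitness is 0.
    """
    if cost_slope < 0:
        raise ValueError("cost_slope must be non-negative")
    interp, x, y = _interp_table(curve, "velocity_m_per_s")
    gs = x[x >= cliff_threshold]
    if gs.size < 3:
        raise ValueError("curve must cover the range above the cliff")
    net = y[x >= cliff_threshold] - cost_slope * gs
    lo, hi = float(net.min()), float(net.max())
    if hi <= lo:
        raise ValueError("net benefit is flat; nothing to normalize")

    def fn(g):
        scaled = (interp(g) - cost_slope * np.asarray(g, dtype=float) - lo) / (hi - lo)
        return np.where(g >= cliff_threshold, np.clip(scaled, 0.0, 1.0), 0.0)

    return FitnessFunction(fn=fn, domain=domain, label=f"velocity_minus_cost_{cost_slope:g}")


def apd_fitness(
    curve: pd.DataFrame,
    scale: float = 0.5,
    cliff_threshold: float = 3.0,
    column: str = "apd50_ms",
    domain: str = "g_k",
) -> FitnessFunction:
    """Selection for short action potentials, over a low-G_K conduction cliff.

    The tabulated action potential duration (falling in G_K) is inverted
    and rescaled so fitness spans [1 - scale, 1] over the tabulated range,
    making fitness monotone nondecreasing in G_K; below ``cliff_threshold``
    (where conduction fails by repolarization failure) fitness is 0.
    """
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must lie in (0, 1]")
    interp, x, y = _interp_table(curve, column)
    lo, hi = float(np.min(y)), float(np.max(y))
    if hi <= lo:
        raise ValueError("duration curve is flat; nothing to invert")

    def fn(g):
        inverted = 1.0 - scale * (interp(g) - lo) / (hi - lo)
        return np.where(np.asarray(g, dtype=float) >= cliff_threshold, inverted, 0.0)

    return FitnessFunction(fn=fn, domain=domain, label=f"apd_inverted_{scale:g}")


@dataclass(frozen=True)
class Region2D:
    """The viable region of (G_Na, G_K) space bounded by fitness cliffs.

    Boundaries are piecewise-linear curves sampled by bisection: the minimum
    conducting G_Na as a function of G_K, the conducting G_K window, and
    (optionally) the minimum G_K with Type 3 firing.  Boundary membership is
    inclusive.
    """

    g_k_samples: tuple[float, ...]
    na_min_values: tuple[float, ...]  # conduction cliff G_Na(G_K)
    k_min: float  # repolarization-failure edge (at reference G_Na)
    k_max: float  # conduction-failure upper K edge
    k_type3_min: float | None = None  # excitability cliff (None: not required)
    g_na_max: float = 1000.0

    def na_min(self, g_k) -> np.ndarray:
        return np.interp(g_k, self.g_k_samples, self.na_min_values)

    def contains(self, g_na, g_k) -> np.ndarray:
        g_na = np.asarray(g_na, dtype=float)
        g_k = np.asarray(g_k, dtype=float)
        k_lo = self.k_min if self.k_type3_min is None else max(self.k_min, self.k_type3_min)
        inside = (
            (g_na >= self.na_min(g_k))
            & (g_k >= k_lo)
            & (g_k <= self.k_max)
            & (g_na <= self.g_na_max)
        )
        out_of_bounds = g_na > self.g_na_max
        if np.any(out_of_bounds):
            warnings.warn("phenotype outside landscape bounds; fitness set to 0")
            inside = inside & ~out_of_bounds
        return inside


def region_fitness_2d(region: Region2D) -> FitnessFunction:
    """Indicator fitness: 1 inside the viable 2D region, 0 outside."""
    return FitnessFunction(
        fn=lambda g_na, g_k: region.contains(g_na, g_k).astype(float),
        domain="2d",
        label="region_conducts_type3",
    )
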