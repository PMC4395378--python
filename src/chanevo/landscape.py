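"""Sweeps of (G_Na, G_K) conductance space: thresholds, curves, tables.

The physiological landscape over sodium/potassium conductance space has two
kinds of structure: sharp discontinuities (conduction failure, the Type 3 to
Type 2 excitability transition) located here by bisection over cable
simulations, and smooth metric surfaces (conduction velocity, sodium flux
per action potential, action potential duration) tabulated on conductance
grids.  Fitness functions consume the thresholds directly and interpolate
the tabulated curves, so that per-individual evaluation during evolution
never runs a cable simulation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .cable import (
    CableParams,
    Conductances,
    Excitability,
    analyze_trace,
    classify_excitability,
    conducts,
    simulate,
)

__all__ = [
    "find_threshold",
    "velocity_curve",
    "metric_curve",
    "find_velocity_peak",
    "LandscapeTable",
    "build_landscape",
    "build_region2d",
]

Axis = Literal["na", "k"]
Predicate = Literal["conducts", "type3"]

CONDUCTION_TEST_TC = 26.0
CONDUCTION_WINDOW_MS = 30.0
SWEEP_TC = 18.5


def _conduction_params(params: CableParams | None, tc: float) -> CableParams:
    base = params or CableParams()
    return replace(base, temperature_c=tc, t_total_ms=CONDUCTION_WINDOW_MS)


def _make_predicate(
    predicate: Predicate | Callable[[float], bool],
    axis: Axis,
    fixed_value: float,
    tc: float,
    params: CableParams | None,
) -> Callable[[float], bool]:
    if callable(predicate):
        return predicate
    if predicate == "conducts":
        p = _conduction_params(params, tc)

        def check(g: float) -> bool:
            g_na, g_k = (g, fixed_value) if axis == "na" else (fixed_value, g)
            return conducts(p, g_na, g_k)

    elif predicate == "type3":
        p = params or CableParams()

        def check(g: float) -> bool:
            g_na, g_k = (g, fixed_value) if axis == "na" else (fixed_value, g)
            cond = Conductances.fitted(g_na, g_k, p)
            return classify_excitability(p, cond, temperature_c=tc) is Excitability.TYPE3

    else:
        raise ValueError(f"unknown predicate {predicate!r}")
    return check


def find_threshold(
    axis: Axis,
    fixed_value: float,
    predicate: Predicate | Callable[[float], bool] = "conducts",
    tc: float = CONDUCTION_TEST_TC,
    bracket: tuple[float, float] = (40.0, 140.0),
    params: CableParams | None = None,
    granularity: float = 1.0,
) -> float:
    """Locate a functional discontinuity along one conductance axis.

    Bisects the ``axis`` conductance between ``bracket`` ends (which must
    disagree on the predicate) down to ``granularity`` (default 1 mS/cm^2,
    the printed precision of the thresholds) and returns the smallest --
    or, when the predicate holds at the lower bracket end, the largest --
    conductance at which the predicate holds.  ``predicate`` is a named
    physiological test ("conducts", "type3") or any monotone boolean
    callable of the swept conductance.
    """
    check = _make_predicate(predicate, axis, fixed_value, tc, params)
    lo, hi = (float(b) for b in bracket)
    if lo >= hi:
        raise ValueError("bracket must be increasing")
    # snap to the granularity grid
    lo = np.floor(lo / granularity) * granularity
    hi = np.ceil(hi / granularity) * granularity
    ok_lo, ok_hi = check(lo), check(hi)
    if ok_lo == ok_hi:
        raise ValueError(
            f"predicate {predicate!r} is {ok_lo} at both bracket ends {lo}, {hi}"
        )
    while hi - lo > granularity * (1 + 1e-9):
        mid = lo + np.round((hi - lo) / (2 * granularity)) * granularity
        if mid in (lo, hi):
            break
        if check(mid) == ok_hi:
            hi = mid
        else:
            lo = mid
    # the edge where the predicate holds
    return hi if ok_hi else lo


@dataclass
class SweepResult:
    """A 1D metric sweep along one conductance axis."""

    axis: Axis
    fixed_value: float
    table: pd.DataFrame
    tc: float

    @property
    def peak_conductance(self) -> float:
        t = self.table
        return float(t.loc[t["velocity_m_per_s"].idxmax(), "conductance"])


def metric_curve(
    axis: Axis,
    fixed_value: float,
    values: Sequence[float],
    tc: float = SWEEP_TC,
    params: CableParams | None = None,
    require_conduction: bool = True,
) -> SweepResult:
    """Tabulate APMetrics along a 1D conductance sweep.

    Every requested point is simulated; a non-conducting point raises unless
    ``require_conduction`` is False, in which case it is flagged in the
    ``conducted`` column (never silently dropped).
    """
    base = params or CableParams()
    p = replace(base, temperature_c=tc)
    rows = []
    for g in values:
        g_na, g_k = (g, fixed_value) if axis == "na" else (fixed_value, g)
        cond = Conductances.fitted(g_na, g_k, p)
        metrics = analyze_trace(simulate(p, cond))
        if require_conduction and not metrics.conducted:
            raise ValueError(
                f"sweep point {axis}={g} (fixed={fixed_value}) does not conduct"
            )
        rows.append(
            {
                "conductance": float(g),
                "g_na": g_na,
                "g_k": g_k,
                "conducted": metrics.conducted,
                "velocity_m_per_s": metrics.velocity_m_per_s,
                "na_flux_nc_per_cm2": metrics.na_flux_nc_per_cm2,
                "apd50_ms": metrics.apd50_ms,
                "apd90_ms": metrics.apd90_ms,
            }
        )
    return SweepResult(axis=axis, fixed_value=fixed_value, table=pd.DataFrame(rows), tc=tc)


def velocity_curve(
    axis: Axis,
    fixed_value: float,
    values: Sequence[float],
    tc: float = SWEEP_TC,
    params: CableParams | None = None,
) -> SweepResult:
    """Conduction velocity along a 1D sweep (all points must conduct)."""
    return metric_curve(axis, fixed_value, values, tc=tc, params=params)


def find_velocity_peak(
    fixed_g_k: float = 36.0,
    tc: float = SWEEP_TC,
    coarse: tuple[float, float, float] = (300.0, 600.0, 20.0),
    refine_halfwidth: float = 40.0,
    refine_step: float = 10.0,
    params: CableParams | None = None,
) -> tuple[float, SweepResult]:
    """Location of the conduction-velocity maximum along the G_Na axis.

    Coarse scan to bracket the maximum, then a finer local scan with a
    parabolic fit through the refined samples.  The curve is extremely flat
    near its maximum (fractional velocity changes ~1e-4 over tens of
    mS/cm^2), so the parabolic fit is the stable estimator.
    """
    lo, hi, step = coarse
    grid = np.arange(lo, hi + step / 2, step)
    sweep = velocity_curve("na", fixed_g_k, grid, tc=tc, params=params)
    g0 = sweep.peak_conductance
    fine = np.arange(g0 - refine_halfwidth, g0 + refine_halfwidth + 1e-9, refine_step)
    sweep_fine = velocity_curve("na", fixed_g_k, fine, tc=tc, params=params)
    t = sweep_fine.table
    coeff = np.polyfit(t["conductance"], t["velocity_m_per_s"], 2)
    g_peak = float(-coeff[1] / (2 * coeff[0]))
    return g_peak, sweep_fine


def build_region2d(
    g_k_samples: Sequence[float] = (24.0, 30.0, 36.0, 44.0, 52.0),
    reference_g_na: float = 120.0,
    require_type3: bool = True,
    params: CableParams | None = None,
    na_bracket: tuple[float, float] = (40.0, 160.0),
    type3_bracket: tuple[float, float] = (18.0, 30.0),
):
    """Bound the viable (G_Na, G_K) region by per-axis bisections.

    The conduction cliff G_Na(G_K) is sampled at ``g_k_samples`` and
    interpolated piecewise-linearly; the conducting G_K window and the
    Type 3 excitability edge are located at ``reference_g_na`` and treated
    as horizontal boundaries (both vary only weakly with G_Na near the
    experimentally relevant conductances).  Returns a
    :class:`chanevo.fitness.Region2D`.
    """
    from .fitness import Region2D

    na_min = tuple(
        find_threshold("na", g_k, "conducts", bracket=na_bracket, params=params)
        for g_k in g_k_samples
    )
    k_min = find_threshold(
        "k", reference_g_na, "conducts", bracket=(1.0, 20.0), params=params
    )
    k_max = find_threshold(
        "k", reference_g_na, "conducts", bracket=(60.0, 120.0), params=params
    )
    k_type3 = None
    if require_type3:
        k_type3 = find_threshold(
            "k", reference_g_na, "type3", tc=6.3, bracket=type3_bracket, params=params
        )
    return Region2D(
        g_k_samples=tuple(float(g) for g in g_k_samples),
        na_min_values=na_min,
        k_min=float(k_min),
        k_max=float(k_max),
        k_type3_min=None if k_type3 is None else float(k_type3),
    )


# ---------------------------------------------------------------------------
# 2D landscape tables with a file cache
# ---------------------------------------------------------------------------


@dataclass
class LandscapeTable:
    """Per-point metrics on a rectangular (G_Na, G_K) grid."""

    table: pd.DataFrame
    metadata: dict

    COLUMNS = (
        "g_na",
        "g_k",
        "conducted",
        "velocity_m_per_s",
        "na_flux",
        "apd50_ms",
        "apd90_ms",
        "excitability",
    )

    def save(self, path: Path | str) -> None:
        path = Path(path)
        self.table.to_csv(path, index=False)
        path.with_suffix(".json").write_text(json.dumps(self.metadata, indent=1))

    @classmethod
    def load(cls, path: Path | str) -> "LandscapeTable":
        path = Path(path)
        table = pd.read_csv(path)
        if "excitability" in table:
            table["excitability"] = table["excitability"].fillna("").astype(str)
        metadata = json.loads(path.with_suffix(".json").read_text())
        return cls(table=table, metadata=metadata)


def _grid_hash(g_na_values, g_k_values, tc, params: CableParams, with_excitability) -> str:
    payload = {
        "g_na": [float(g) for g in g_na_values],
        "g_k": [float(g) for g in g_k_values],
        "tc": tc,
        "params": asdict(params),
        "excitability": bool(with_excitability),
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def build_landscape(
    g_na_values: Sequence[float],
    g_k_values: Sequence[float],
    tc: float = CONDUCTION_TEST_TC,
    params: CableParams | None = None,
    with_excitability: bool = False,
    cache_dir: Path | str | None = None,
) -> LandscapeTable:
    """Evaluate APMetrics (optionally excitability class) on a full grid.

    Deterministic given the grid and parameters; when ``cache_dir`` is
    given the result is stored as CSV + JSON sidecar keyed by a parameter
    hash and reloaded bit-identically on subsequent calls.
    """
    base = params or CableParams()
    p = replace(base, temperature_c=tc, t_total_ms=CONDUCTION_WINDOW_MS)
    key = _grid_hash(g_na_values, g_k_values, tc, base, with_excitability)
    cache_path = None
    if cache_dir is not None:
        cache_path = Path(cache_dir) / f"landscape_{key}.csv"
        if cache_path.exists():
            cached = LandscapeTable.load(cache_path)
            if cached.metadata.get("key") == key:
                return cached
            # stale or foreign cache file: fall through and recompute
            import warnings

            warnings.warn("landscape cache key mismatch; recomputing")
    rows = []
    for g_k in g_k_values:
        for g_na in g_na_values:
            cond = Conductances.fitted(float(g_na), float(g_k), p)
            metrics = analyze_trace(simulate(p, cond))
            excit = ""
            if with_excitability and metrics.conducted:
                excit = classify_excitability(base, cond).name
            rows.append(
                {
                    "g_na": float(g_na),
                    "g_k": float(g_k),
                    "conducted": metrics.conducted,
                    "velocity_m_per_s": metrics.velocity_m_per_s,
                    "na_flux": metrics.na_flux_nc_per_cm2,
                    "apd50_ms": metrics.apd50_ms,
                    "apd90_ms": metrics.apd90_ms,
                    "excitability": excit,
                }
            )
    table = pd.DataFrame(rows, columns=list(LandscapeTable.COLUMNS))
    meta = {
        "key": key,
        "tc": tc,
        "n_g_na": len(list(g_na_values)),
        "n_g_k": len(list(g_k_values)),
        "dt_ms": base.dt_ms,
        "dx_cm": base.dx_cm,
    }
    result = LandscapeTable(table=table, metadata=meta)
    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        result.save(cache_path)
    return result
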