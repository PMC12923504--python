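"""RSLR trajectories, threshold identification, and scenario sweeps.

The RSLR threshold for a target year is the constant rate whose remaining
wetland area at that year sits midway between the areas obtained under the
low anchor (the current rate, 9 mm/yr by default) and the high anchor
(20 mm/yr). Because remaining area is monotone non-increasing in the rate,
the threshold is located by bisection after a coarse monotonicity check;
if the check fails (it should not, but degenerate landscapes exist), a
grid scan with linear interpolation is used and the result flagged.

Acceleration scenarios ramp the rate linearly from the current rate to a
target (typically a threshold) by some year, then hold it constant.
Restoration scenarios rerun the simulator with accretion/erosion
multipliers, mimicking interventions such as sediment diversions (more
accretion) or living shorelines (less erosion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import SimParams, SimResult, SimState, Surfaces, run
import dataclasses


class ThresholdNotFound(ValueError):
    """Raised when the anchor runs show no loss contrast in the rate range."""


@dataclass(frozen=True)
class RSLRTrajectory:
    """Per-year RSLR rate series (m/yr) over [start_year, end_year]."""

    start_year: int
    end_year: int
    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ValueError("end_year must be >= start_year")
        if len(self.rates) != self.end_year - self.start_year + 1:
            raise ValueError("rate series must cover every year in range")
        if any(r < 0 for r in self.rates):
            raise ValueError("RSLR rates must be non-negative")

    def rate_at(self, year: int) -> float:
        if not (self.start_year <= year <= self.end_year):
            raise ValueError(f"year {year} outside trajectory range "
                             f"[{self.start_year}, {self.end_year}]")
        return self.rates[year - self.start_year]


def make_trajectory(kind: str, start_rate: float, start_year: int,
                    end_year: int, target_rate: float | None = None,
                    ramp_end_year: int | None = None) -> RSLRTrajectory:
    """Build a constant or ramp trajectory (rates in m/yr).

    ``constant``: uniform at ``start_rate``. ``ramp``: linear from
    ``start_rate`` at ``start_year`` to ``target_rate`` at
    ``ramp_end_year``, constant afterwards.
    """
    years = np.arange(start_year, end_year + 1)
    if kind == "constant":
        rates = np.full(years.size, float(start_rate))
    elif kind == "ramp":
        if target_rate is None or ramp_end_year is None:
            raise ValueError("ramp needs target_rate and ramp_end_year")
        if not (start_year <= ramp_end_year <= end_year):
            raise ValueError("ramp_end_year outside [start_year, end_year]")
        rates = np.where(
            years >= ramp_end_year, float(target_rate),
            start_rate + (target_rate - start_rate)
            * (years - start_year) / (ramp_end_year - start_year))
    else:
        raise ValueError(f"unknown trajectory kind {kind!r}")
    return RSLRTrajectory(start_year, end_year, tuple(float(r) for r in rates))


@dataclass
class ThresholdResult:
    """Outcome of a threshold search for one target year."""

    target_year: int
    threshold_rate: float          # m/yr
    area_at_low: float             # ha at the low anchor
    area_at_high: float            # ha at the high anchor
    midway_area: float             # ha
    trace: list                    # (rate, area) evaluations in order
    method: str = "bisection"      # or "grid_scan" when non-monotone

    @property
    def threshold_mm_yr(self) -> float:
        return self.threshold_rate * 1000.0


def _constant_area(initial: SimState, params: SimParams, surfaces: Surfaces,
                   rate: float, target_year: int, horizon: int,
                   cache: dict) -> float:
    """Wetland area (ha) at ``target_year`` under a constant rate, cached."""
    key = round(rate, 12)
    result = cache.get(key)
    if result is None or result.years[-1] < target_year:
        traj = make_trajectory("constant", rate, initial.year, horizon)
        result = run(initial, traj, params, surfaces)
        cache[key] = result
    return result.area_at(target_year)


def find_threshold(initial: SimState, params: SimParams, surfaces: Surfaces,
                   target_year: int, r_lo: float = 0.009,
                   r_hi: float = 0.020, tol: float = 1e-4,
                   horizon: int | None = None,
                   cache: dict | None = None) -> ThresholdResult:
    """Locate the RSLR threshold for ``target_year`` by the midway criterion.

    Every candidate rate is simulated (no interpolation between runs).
    ``tol`` is the bisection bracket width in m/yr. ``horizon`` lets
    callers reuse one run across several target years; ``cache`` (a dict)
    can be shared across calls to avoid re-simulating anchor rates.

    Raises
    ------
    ThresholdNotFound
        If the low- and high-anchor areas coincide (no loss contrast).
    """
    if r_lo >= r_hi:
        raise ValueError("need r_lo < r_hi")
    if target_year <= initial.year:
        raise ValueError("target_year must lie after the start year")
    horizon = max(horizon or target_year, target_year)
    cache = {} if cache is None else cache
    trace: list[tuple[float, float]] = []

    def area(rate: float) -> float:
        a = _constant_area(initial, params, surfaces, rate, target_year,
                           horizon, cache)
        trace.append((rate, a))
        return a

    a_lo, a_hi = area(r_lo), area(r_hi)
    if a_lo == a_hi:
        raise ThresholdNotFound(
            f"no threshold in range: area at {target_year} is {a_lo:.3f} ha "
            f"at both anchor rates")
    a_mid = 0.5 * (a_lo + a_hi)

    # Coarse monotonicity check on a 5-point grid before trusting bisection.
    grid = np.linspace(r_lo, r_hi, 5)
    grid_areas = [area(r) for r in grid]
    monotone = all(grid_areas[i] >= grid_areas[i + 1] - 1e-9
                   for i in range(len(grid_areas) - 1))

    if monotone:
        lo, hi = r_lo, r_hi
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if area(mid) >= a_mid:
                lo = mid
            else:
                hi = mid
        rate = 0.5 * (lo + hi)
        method = "bisection"
    else:  # fall back to a dense scan + linear interpolation, flagged
        scan = np.arange(r_lo, r_hi + 0.5 * tol, max(tol, 5e-5))
        scan_areas = np.asarray([area(r) for r in scan])
        j = int(np.argmin(np.abs(scan_areas - a_mid)))
        rate = float(scan[j])
        if 0 < j < len(scan) - 1 and scan_areas[j + 1] != scan_areas[j - 1]:
            frac = (a_mid - scan_areas[j - 1]) \
                / (scan_areas[j + 1] - scan_areas[j - 1])
            rate = float(scan[j - 1] + frac * (scan[j + 1] - scan[j - 1]))
            rate = float(np.clip(rate, r_lo, r_hi))
        method = "grid_scan"
    return ThresholdResult(target_year, float(rate), a_lo, a_hi, a_mid,
                           trace, method)


def find_thresholds(initial: SimState, params: SimParams, surfaces: Surfaces,
                    target_years: "list[int]", r_lo: float = 0.009,
                    r_hi: float = 0.020, tol: float = 1e-4
                    ) -> dict[int, ThresholdResult]:
    """Thresholds for several target years, sharing constant-rate runs."""
    cache: dict = {}
    horizon = max(target_years)
    return {year: find_threshold(initial, params, surfaces, year, r_lo, r_hi,
                                 tol, horizon=horizon, cache=cache)
            for year in sorted(target_years)}


# ---------------------------------------------------------------------------
# Scenario suites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """One named run: a trajectory plus accretion/erosion multipliers."""

    name: str
    trajectory: RSLRTrajectory
    acc_multiplier: float = 1.0
    ero_multiplier: float = 1.0


def run_scenario_suite(initial: SimState, params: SimParams,
                       surfaces: Surfaces,
                       specs: "list[ScenarioSpec]"
                       ) -> tuple[pd.DataFrame, dict[str, SimResult]]:
    """Run each scenario; return a long table and the per-scenario results.

    The table has columns (scenario, year, wetland_ha, wetland_pct), with
    percentages relative to the total grid area.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate scenario names")
    total_ha = initial.meta.n_rows * initial.meta.n_cols \
        * initial.meta.cell_area_m2 / 1.0e4
    rows = []
    results: dict[str, SimResult] = {}
    for spec in specs:
        p = dataclasses.replace(params, acc_multiplier=spec.acc_multiplier,
                                ero_multiplier=spec.ero_multiplier)
        result = run(initial, spec.trajectory, p, surfaces)
        results[spec.name] = result
        for year, ha in zip(result.years, result.wetland_ha):
            rows.append((spec.name, int(year), float(ha),
                         100.0 * float(ha) / total_ha))
    table = pd.DataFrame(rows, columns=["scenario", "year", "wetland_ha",
                                        "wetland_pct"])
    return table, results


def restoration_specs(trajectory: RSLRTrajectory) -> "list[ScenarioSpec]":
    """The standard restoration sweep on one forcing trajectory.

    Baseline, accretion multipliers 1.2-2.0, halved erosion, and the
    aggressive combination (doubled accretion + halved erosion).
    """
    specs = [ScenarioSpec("baseline", trajectory)]
    for m in (1.2, 1.4, 1.6, 1.8, 1.9, 2.0):
        specs.append(ScenarioSpec(f"acc_x{m:g}", trajectory, acc_multiplier=m))
    specs.append(ScenarioSpec("ero_x0.5", trajectory, ero_multiplier=0.5))
    specs.append(ScenarioSpec("acc_x2_ero_x0.5", trajectory,
                              acc_multiplier=2.0, ero_multiplier=0.5))
    return specs
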