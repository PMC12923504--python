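"""Annual-step elevation and land-cover dynamics under relative sea-level rise.

Each year, every wetland cell updates its elevation by the bookkeeping
identity

    Elev_t = Elev_{t-1} - RSLR_t + Acc_t - Ero_t        (all rates m/yr)

and any wetland cell that ends the year below mean low water converts —
irreversibly — to open water. Elevation is tracked relative to the current
sea level: the RSLR rate is subtracted from elevation while the tidal
levels (MLW/MHW) stay fixed. Open-water cells feel only -RSLR.

Accretion combines an inorganic term (suspended sediment settling during
inundation, amplified by aboveground-biomass trapping) and an organic term
(linear in belowground biomass):

    Acc = m_acc * [ k_settle * TSS * H(z) * (1 + k_trap * min(B_ag/B_ref, 1))
                    / rho_bulk  +  k_org * B_bg ]

with TSS in g/m^3 (numerically equal to mg/L), rho_bulk in g/m^3, and H(z)
the hydroperiod proxy — the inundated fraction of time, linear between MHW
(never flooded) and MLW (always flooded). The hydroperiod proxy stands in
for a full hydrodynamic submodel, which is out of scope here. Erosion acts
only at the marsh edge, scaled by the fraction of 4-neighbors that are
open water.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .grid import WATER, WETLAND, Grid, GridMeta, require_aligned

#: loss_year sentinel: cell still wetland at the end of the run.
PERSISTENT = -1
#: loss_year sentinel: cell was not wetland at the start.
NEVER_WETLAND = -9999


@dataclass(frozen=True)
class SimParams:
    """Biophysical parameters of the annual step.

    All rates are m/yr internally; user-facing configs use mm/yr and are
    converted exactly once at ingest. ``bulk_density`` is g/cm^3 as
    reported by monitoring programs and converted to g/m^3 internally.
    """

    mlw: float = -0.15            # m, mean low water (conversion level)
    mhw: float = 0.15             # m, mean high water
    bulk_density: float = 0.289   # g/cm^3, deposited sediment
    k_settle: float = 60.0        # m/yr effective capture velocity
    k_trap: float = 1.0           # aboveground-biomass trapping gain
    b_ag_ref: float = 1000.0      # g/m^2 reference aboveground biomass
    k_org: float = 4.0e-6         # m/yr per g/m^2 belowground biomass
    e_base: float = 0.02          # m/yr edge erosion scale
    acc_multiplier: float = 1.0   # restoration levers
    ero_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.mhw <= self.mlw:
            raise ValueError("need mhw > mlw")
        if self.bulk_density <= 0:
            raise ValueError("bulk_density must be positive")
        for name in ("k_settle", "k_trap", "b_ag_ref", "k_org", "e_base",
                     "acc_multiplier", "ero_multiplier"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def bulk_density_g_m3(self) -> float:
        return self.bulk_density * 1.0e6


@dataclass(frozen=True)
class Surfaces:
    """Model-input surfaces aligned to the simulation grid.

    ``tss`` is a static mg/L field. Biomass can be either a static g/m^2
    field or an ``(intercept, slope)`` pair of the fitted
    biomass-elevation relation, in which case biomass is re-evaluated at
    the *current* elevation every step (truncated at zero) so vegetation
    responds as the marsh drowns.
    """

    tss: np.ndarray
    ab_biomass: "np.ndarray | tuple[float, float]"
    bg_biomass: "np.ndarray | tuple[float, float]"

    def ab(self, elevation: np.ndarray) -> np.ndarray:
        return _eval_biomass(self.ab_biomass, elevation)

    def bg(self, elevation: np.ndarray) -> np.ndarray:
        return _eval_biomass(self.bg_biomass, elevation)


def _eval_biomass(spec, elevation: np.ndarray) -> np.ndarray:
    if isinstance(spec, tuple):
        intercept, slope = spec
        return np.maximum(intercept + slope * elevation, 0.0)
    return np.asarray(spec, dtype=float)


@dataclass
class SimState:
    """Simulation state at the end of a given year."""

    year: int
    elevation: np.ndarray
    landcover: np.ndarray
    loss_year: np.ndarray
    meta: GridMeta

    def copy(self) -> "SimState":
        return SimState(self.year, self.elevation.copy(),
                        self.landcover.copy(), self.loss_year.copy(),
                        self.meta)

    @property
    def wetland_ha(self) -> float:
        return float((self.landcover == WETLAND).sum()
                     * self.meta.cell_area_m2 / 1.0e4)


@dataclass
class SimResult:
    """Yearly wetland-area series plus the final state."""

    years: np.ndarray
    wetland_ha: np.ndarray
    final_state: SimState

    @property
    def loss_year(self) -> np.ndarray:
        return self.final_state.loss_year

    def area_at(self, year: int) -> float:
        idx = np.searchsorted(self.years, year)
        if idx >= len(self.years) or self.years[idx] != year:
            raise ValueError(f"year {year} not in simulated range")
        return float(self.wetland_ha[idx])


def initial_state(dem: Grid, landcover: Grid, start_year: int) -> SimState:
    """Build the year-0 state; loss_year starts as PERSISTENT on wetland."""
    require_aligned(dem, landcover)
    lc = np.asarray(landcover.data).astype(int)
    loss = np.where(lc == WETLAND, PERSISTENT, NEVER_WETLAND)
    return SimState(start_year, np.asarray(dem.data, dtype=float).copy(),
                    lc.copy(), loss, dem.meta)


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

def hydroperiod(elevation_m, params: SimParams):
    """Inundated fraction of time: 1 at/below MLW, 0 at/above MHW, linear
    in between. Works elementwise on scalars or arrays."""
    frac = (params.mhw - np.asarray(elevation_m, dtype=float)) \
        / (params.mhw - params.mlw)
    return np.clip(frac, 0.0, 1.0)


def accretion_rate(tss_mgL, ab_biomass, bg_biomass, elevation_m,
                   params: SimParams, water=False):
    """Accretion rate, m/yr, elementwise; zero on open-water cells.

    Linear in TSS and in belowground biomass; non-increasing in elevation
    for fixed biomass. The trapping term saturates at ``b_ag_ref``.
    """
    tss = np.asarray(tss_mgL, dtype=float)
    ab = np.asarray(ab_biomass, dtype=float)
    bg = np.asarray(bg_biomass, dtype=float)
    if (np.any(tss < 0) or np.any(ab < 0) or np.any(bg < 0)):
        raise ValueError("accretion inputs must be non-negative")
    h = hydroperiod(elevation_m, params)
    trap = 1.0 + params.k_trap * np.minimum(ab / params.b_ag_ref, 1.0)
    inorganic = params.k_settle * tss * h * trap / params.bulk_density_g_m3
    acc = params.acc_multiplier * (inorganic + params.k_org * bg)
    return np.where(np.asarray(water, dtype=bool), 0.0, acc)


def water_neighbor_fraction(landcover: np.ndarray) -> np.ndarray:
    """Fraction of 4-neighbors that are open water (outside counts as land)."""
    water = (landcover == WATER).astype(np.float64)
    count = np.zeros_like(water)
    count[1:, :] += water[:-1, :]
    count[:-1, :] += water[1:, :]
    count[:, 1:] += water[:, :-1]
    count[:, :-1] += water[:, 1:]
    return count / 4.0


def erosion_rate(landcover: np.ndarray, params: SimParams) -> np.ndarray:
    """Edge erosion, m/yr: exposure-scaled on wetland, zero elsewhere."""
    exposure = water_neighbor_fraction(landcover)
    ero = params.ero_multiplier * params.e_base * exposure
    return np.where(landcover == WETLAND, ero, 0.0)


# ---------------------------------------------------------------------------
# Stepping
# ---------------------------------------------------------------------------

def step(state: SimState, params: SimParams, rslr_rate: float,
         surfaces: Surfaces) -> SimState:
    """Advance one year (synchronous update across cells).

    Wetland cells receive the full elevation identity; water cells only
    -RSLR. Conversion (wetland below MLW becomes water, loss_year set) is
    checked after the whole field has updated, so cell order is
    irrelevant. Returns a new state; the input is untouched.
    """
    if rslr_rate < 0:
        raise ValueError("RSLR rate must be non-negative")
    if np.asarray(surfaces.tss).shape != state.elevation.shape:
        raise ValueError("surfaces misaligned with simulation grid")
    year = state.year + 1
    wet = state.landcover == WETLAND
    acc = accretion_rate(surfaces.tss, surfaces.ab(state.elevation),
                         surfaces.bg(state.elevation), state.elevation,
                         params, water=~wet)
    ero = erosion_rate(state.landcover, params)
    elevation = state.elevation - rslr_rate + np.where(wet, acc - ero, 0.0)

    converted = wet & (elevation < params.mlw)
    landcover = state.landcover.copy()
    landcover[converted] = WATER
    loss_year = state.loss_year.copy()
    loss_year[converted] = year
    return SimState(year, elevation, landcover, loss_year, state.meta)


def run(initial: SimState, trajectory, params: SimParams,
        surfaces: Surfaces) -> SimResult:
    """Run the simulator over an RSLR trajectory, recording area yearly.

    ``trajectory`` must provide ``rate_at(year)`` for every year in
    ``(initial.year, end_year]`` (see :mod:`marshline.scenarios`).
    """
    if trajectory.start_year > initial.year or trajectory.end_year <= initial.year:
        raise ValueError(
            f"trajectory [{trajectory.start_year}, {trajectory.end_year}] "
            f"does not cover the run starting {initial.year}")
    state = initial.copy()
    years = [state.year]
    areas = [state.wetland_ha]
    for year in range(initial.year + 1, trajectory.end_year + 1):
        state = step(state, params, trajectory.rate_at(year), surfaces)
        years.append(year)
        areas.append(state.wetland_ha)
    return SimResult(np.asarray(years), np.asarray(areas, dtype=float), state)


def calibrate_accretion(params: SimParams, surfaces: Surfaces,
                        elevation: np.ndarray, landcover: np.ndarray,
                        observation_cells: "list[tuple[int, int]]",
                        target_accretion: float) -> SimParams:
    """Scale ``k_settle`` and ``k_org`` so mean accretion at the observation
    cells matches a measured target (m/yr).

    Accretion is linear in the pair, so one common factor suffices; the
    calibrated mean matches the target to ~1e-9 relative.
    """
    if target_accretion <= 0:
        raise ValueError("target accretion must be positive")
    if not observation_cells:
        raise ValueError("need at least one observation cell")
    rows, cols = zip(*observation_cells)
    acc = accretion_rate(surfaces.tss, surfaces.ab(elevation),
                         surfaces.bg(elevation), elevation, params,
                         water=(landcover != WETLAND))
    mean_acc = float(np.mean(acc[np.asarray(rows), np.asarray(cols)]))
    if mean_acc == 0.0:
        raise ValueError("uncalibrated accretion is zero at every "
                         "observation cell: uncalibratable")
    s = target_accretion / mean_acc
    return dataclasses.replace(params, k_settle=params.k_settle * s,
                               k_org=params.k_org * s)
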