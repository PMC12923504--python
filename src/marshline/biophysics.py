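"""Laboratory arithmetic for the field campaign.

Three conversions connect raw bench measurements to model inputs:

* soil porewater salinity from a fixed-volume (20 ml) distilled-water
  extraction of dried soil, by mass balance — the moisture driven off in
  drying is the porewater volume, taking water density as exactly 1 g/ml;
* inorganic total suspended solids (TSS) from pre/post-ashing filter
  weights and the filtered water volume;
* areal biomass density (g/m²) from quadrat- or core-collected dry mass
  and the collector footprint.

These are deliberately small, total functions: bad measurements (negative
moisture, filters losing mass, zero volumes) raise immediately instead of
being clamped, so data-quality problems surface at ingest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

#: Aboveground quadrat side length, metres (25 x 25 cm quadrat).
QUADRAT_SIDE_M = 0.25
#: Belowground soil-core diameter, metres (4-inch PVC core).
CORE_DIAMETER_M = 0.1016

QUADRAT_AREA_M2 = QUADRAT_SIDE_M ** 2
CORE_AREA_M2 = math.pi * (CORE_DIAMETER_M / 2.0) ** 2


class Collector(Enum):
    QUADRAT = "quadrat"
    CORE = "core"


COLLECTOR_AREA = {Collector.QUADRAT: QUADRAT_AREA_M2, Collector.CORE: CORE_AREA_M2}


@dataclass(frozen=True)
class SoilSample:
    """One dried-soil salinity extraction record."""

    wet_weight_g: float
    dry_weight_g: float
    extract_salinity_ppt: float
    extract_volume_ml: float = 20.0

    def __post_init__(self) -> None:
        if self.dry_weight_g < 0 or self.wet_weight_g <= self.dry_weight_g:
            raise ValueError("need wet_weight_g > dry_weight_g >= 0")
        if self.extract_salinity_ppt < 0:
            raise ValueError("extract salinity must be non-negative")
        if self.extract_volume_ml <= 0:
            raise ValueError("extract volume must be positive")


@dataclass(frozen=True)
class WaterSample:
    """One filtered-and-ashed water sample (inorganic TSS measurement)."""

    filter_after_ashing_mg: float
    filter_plus_solids_after_ashing_mg: float
    volume_filtered_L: float

    def __post_init__(self) -> None:
        if self.filter_plus_solids_after_ashing_mg < self.filter_after_ashing_mg:
            raise ValueError(
                "filter lost mass during filtering+ashing: weighing inconsistency")
        if self.volume_filtered_L <= 0:
            raise ValueError("filtered volume must be positive")


class Pool(Enum):
    LIVE = "live"
    DEAD = "dead"


class Layer(Enum):
    ABOVE = "above"
    BELOW = "below"


@dataclass(frozen=True)
class BiomassSample:
    """Dry biomass from one collector (one depth increment for cores)."""

    dry_mass_g: float
    collector: Collector
    pool: Pool = Pool.LIVE
    layer: Layer = Layer.ABOVE
    depth_increment: int | None = None  # 5-cm increment index for cores

    def __post_init__(self) -> None:
        if self.dry_mass_g < 0:
            raise ValueError("dry mass must be non-negative")


def porewater_salinity(sample: SoilSample) -> float:
    """Soil porewater salinity (ppt) by mass balance.

    The moisture mass lost in drying, at 1 g/ml, is the porewater volume
    in which the extracted salt originally sat::

        S_porewater = S_extract * V_extract / (W_wet - W_dry)
    """
    moisture_ml = sample.wet_weight_g - sample.dry_weight_g  # 1 g == 1 ml
    return sample.extract_salinity_ppt * sample.extract_volume_ml / moisture_ml


def inorganic_tss(sample: WaterSample) -> float:
    """Inorganic total suspended solids, mg/L."""
    mass_mg = (sample.filter_plus_solids_after_ashing_mg
               - sample.filter_after_ashing_mg)
    return mass_mg / sample.volume_filtered_L


def areal_density(sample: BiomassSample) -> float:
    """Areal biomass density, g/m², from dry mass and collector footprint."""
    try:
        area = COLLECTOR_AREA[sample.collector]
    except (KeyError, TypeError):
        raise ValueError(f"unknown collector type {sample.collector!r}") from None
    return sample.dry_mass_g / area


def core_total_density(increment_masses_g: "list[float] | np.ndarray") -> float:
    """Whole-core belowground density: sum the 5-cm increments, then convert.

    The simulator uses a single belowground biomass per location, so the
    depth increments of the 30-cm core are pooled before the area division.
    """
    masses = np.asarray(increment_masses_g, dtype=float)
    if (masses < 0).any():
        raise ValueError("dry mass must be non-negative")
    return areal_density(BiomassSample(float(masses.sum()), Collector.CORE,
                                       layer=Layer.BELOW))


# ---------------------------------------------------------------------------
# Table-level helpers
# ---------------------------------------------------------------------------

def table_to_densities(samples: pd.DataFrame) -> pd.DataFrame:
    """Derive model-ready quantities from a raw field-sample table.

    Adds, per row: ``ab_biomass_gm2`` and ``bg_biomass_gm2`` (areal
    densities), ``porewater_ppt`` and ``tss_mgL``. Expects the column
    dialect written by :mod:`marshline.synthetic` (raw weights, volumes,
    extract salinities).
    """
    out = samples.copy()
    out["ab_biomass_gm2"] = out["ab_dry_g"] / QUADRAT_AREA_M2
    out["bg_biomass_gm2"] = out["bg_dry_g"] / CORE_AREA_M2
    moisture = out["soil_wet_g"] - out["soil_dry_g"]
    if (moisture <= 0).any():
        raise ValueError("soil record with non-positive moisture content")
    out["porewater_ppt"] = out["extract_salinity_ppt"] * 20.0 / moisture
    solids = out["filter_plus_ash_mg"] - out["filter_mg"]
    if (solids < 0).any():
        raise ValueError("filter lost mass: weighing inconsistency")
    if (out["water_volume_L"] <= 0).any():
        raise ValueError("filtered volume must be positive")
    out["tss_mgL"] = solids / out["water_volume_L"]
    return out


def site_summary(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-site means and standard deviations of the derived quantities."""
    derived = table_to_densities(samples)
    cols = ["elevation_m", "ab_biomass_gm2", "bg_biomass_gm2",
            "porewater_ppt", "tss_mgL"]
    g = derived.groupby("site")[cols]
    summary = g.agg(["mean", "std"])
    summary.columns = [f"{c}_{stat}" for c, stat in summary.columns]
    return summary.reset_index()
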