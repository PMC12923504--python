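"""Seeded synthetic inputs: DEM, land cover, TEK class maps, field samples.

The study's LiDAR elevation, wetland-inventory land cover, knowledge-map
rasters, and field tables are not publicly deposited, so this module
fabricates a landscape with the same *structure*: a marsh platform sitting
0.3-0.5 m above the tidal datum, a bay to the south, sinuous dredged
channels cutting the marsh with spoil-bank ridges along them, a low-marsh
fringe grading down toward the water, spatially autocorrelated
micro-topography, and a nested field-sampling design (5 sites x 2 transects
x 3 subsites x 2 replicates) whose biomass increases with elevation and
whose suspended-sediment concentration follows a northing gradient.

Everything is driven by one integer seed, split into named substreams
(dem / tek / samples) so regenerating any component is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .biophysics import CORE_AREA_M2, QUADRAT_AREA_M2
from .grid import NODATA, WATER, WETLAND, Grid, GridMeta, write_grid

#: Dry-to-wet mass ratio used to emit plausible wet weights.
_DRY_FRACTION = 0.35
#: Inorganic fraction of total retained solids on a filter.
_INORGANIC_FRACTION = 1.0 / 1.4

_SUBSTREAMS = {"dem": 0, "tek": 1, "samples": 2}


def _rng(seed: int, name: str) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return np.random.default_rng(children[_SUBSTREAMS[name]])


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic world.

    Defaults encode the study conditions: 2-m cells, a marsh platform at
    0.40 +/- 0.05 m above datum (site elevations 0.3-0.5 m), ~0.3 m tidal
    range centered on the datum, and an initial land fraction of 46.2%.
    """

    n_rows: int = 500
    n_cols: int = 500
    cell_size: float = 2.0
    platform_mean: float = 0.40          # m above datum
    platform_sd: float = 0.05            # m, smoothed micro-topography
    platform_tilt: float = 0.20          # m total rise from bay edge to north
    fringe_width_m: float = 24.0         # low-marsh fringe width
    fringe_low: float = 0.02             # m, marsh elevation at the water edge
    channel_depth: float = 1.0           # m below MLW for channel beds
    spoil_bank_height: float = 0.5       # m above local platform
    n_channels: int = 2
    target_land_fraction: float = 0.462
    mlw: float = -0.15                   # m, mean low water
    mhw: float = 0.15                    # m, mean high water
    biomass_slope: float = 1000.0        # g/m^2 per m elevation
    biomass_intercept: float = 500.0     # g/m^2 at datum
    bg_factor: float = 2.5               # belowground/aboveground scale
    site_sd: float = 20.0                # g/m^2 random site effect
    residual_sd: float = 120.0           # g/m^2 residual noise
    tss_mean: float = 30.0               # mg/L at mid-domain northing
    tss_north_gradient: float = -0.01    # mg/L per m northing
    tss_site_sd: float = 2.0             # mg/L random site effect
    tss_residual_sd: float = 1.5         # mg/L residual noise
    porewater_mean_ppt: float = 21.0     # ppt, typical estuarine salinity here
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if not (0.0 < self.target_land_fraction < 1.0):
            raise ValueError("target_land_fraction must lie in (0, 1)")
        if self.mlw >= self.mhw:
            raise ValueError("need mlw < mhw")
        if self.channel_depth <= 0 or self.cell_size <= 0:
            raise ValueError("channel_depth and cell_size must be positive")


@dataclass
class SyntheticBundle:
    """All synthetic inputs on one aligned grid."""

    dem: Grid
    landcover: Grid
    tek_vulnerability: Grid
    tek_sustainability: Grid
    samples: pd.DataFrame
    spoil_mask: np.ndarray
    config: SynthConfig


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Unit-variance smoothed white noise (correlation length ~sigma cells)."""
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma,
                                    mode="reflect")
    return field / field.std()


def _channel_masks(rng: np.random.Generator, cfg: SynthConfig
                   ) -> np.ndarray:
    """Sinuous 1-3 cell wide channels running north-south into the bay."""
    mask = np.zeros((cfg.n_rows, cfg.n_cols), dtype=bool)
    for k in range(cfg.n_channels):
        start = cfg.n_cols * (k + 1) / (cfg.n_channels + 1)
        start += rng.uniform(-0.05, 0.05) * cfg.n_cols
        drift = ndimage.gaussian_filter1d(rng.normal(0.0, 1.0, cfg.n_rows), 8.0)
        path = np.clip(np.round(start + np.cumsum(drift)), 1,
                       cfg.n_cols - 2).astype(int)
        width = np.clip(np.round(
            2.0 + 1.5 * ndimage.gaussian_filter1d(
                rng.normal(0.0, 1.0, cfg.n_rows), 12.0)), 1, 3).astype(int)
        for row in range(cfg.n_rows):
            lo = path[row] - width[row] // 2
            mask[row, lo:lo + width[row]] = True
    return mask


def _bay_boundary(rng: np.random.Generator, cfg: SynthConfig,
                  channel: np.ndarray) -> np.ndarray:
    """Per-column bay boundary row chosen to realize the target land fraction."""
    wiggle = ndimage.gaussian_filter1d(rng.normal(0.0, 1.0, cfg.n_cols), 20.0)
    wiggle = np.round(3.0 * wiggle / max(wiggle.std(), 1e-12)).astype(int)
    n_total = cfg.n_rows * cfg.n_cols
    target_water = (1.0 - cfg.target_land_fraction) * n_total
    rows = np.arange(cfg.n_rows)[:, None]

    def water_count(b0: int) -> int:
        boundary = np.clip(b0 + wiggle, 1, cfg.n_rows - 1)
        bay = rows >= boundary[None, :]
        return int((bay | channel).sum())

    lo, hi = 1, cfg.n_rows - 1  # water_count is monotone decreasing in b0
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if water_count(mid) > target_water:
            lo = mid
        else:
            hi = mid
    b0 = min((lo, hi), key=lambda b: abs(water_count(b) - target_water))
    return np.clip(b0 + wiggle, 1, cfg.n_rows - 1)


def generate_landscape(config: SynthConfig) -> SyntheticBundle:
    """Generate the full synthetic bundle (DEM, land cover, TEK maps, samples).

    Deterministic for a fixed ``config.seed``. The realized land fraction
    lands within +/-0.03 of ``target_land_fraction``; every channel and bay
    cell sits below mean low water; land cover is WETLAND exactly where the
    DEM is at or above MLW inside the marsh mask.
    """
    cfg = config
    meta = GridMeta(cfg.n_rows, cfg.n_cols, cfg.cell_size)
    rng = _rng(cfg.seed, "dem")

    noise = cfg.platform_sd * _smooth_field(rng, meta.shape, 5.0)
    channel = _channel_masks(rng, cfg)
    boundary = _bay_boundary(rng, cfg, channel)
    rows = np.arange(cfg.n_rows)[:, None]
    bay = rows >= boundary[None, :]
    water_mask = bay | channel
    marsh_mask = ~water_mask

    # Distance (m) from each marsh cell to the nearest water cell.
    dist_m = ndimage.distance_transform_edt(marsh_mask) * cfg.cell_size

    # Platform rises gently away from the bay (paper-consistent 0.3-0.5 m
    # spread) and grades down to a low-marsh fringe along every water edge.
    rel_north = np.clip((boundary[None, :] - rows) / np.maximum(boundary, 1),
                        0.0, 1.0)
    platform = cfg.platform_mean + cfg.platform_tilt * (rel_north - 0.5)
    blend = np.clip(dist_m / cfg.fringe_width_m, 0.0, 1.0)
    elev = cfg.fringe_low + blend * (platform - cfg.fringe_low)
    elev += noise * (0.3 + 0.7 * blend)

    # Spoil banks: one-cell ridges hugging the channels, above the platform.
    spoil = (ndimage.binary_dilation(channel, iterations=1)
             & ~channel & marsh_mask)
    elev[spoil] = platform[spoil] + cfg.spoil_bank_height + noise[spoil]

    bed = cfg.mlw - cfg.channel_depth
    elev[bay] = np.minimum(bed - 0.3 + 0.2 * noise[bay], cfg.mlw - 0.05)
    elev[channel] = np.minimum(bed + 0.1 * noise[channel], cfg.mlw - 0.05)

    landcover = np.where(marsh_mask & (elev >= cfg.mlw), WETLAND, WATER)

    dem = Grid(elev, meta)
    lc = Grid(landcover, meta)
    tek_v, tek_s = _tek_maps(cfg, meta, elev, landcover, dist_m, spoil)
    bundle = SyntheticBundle(dem, lc, tek_v, tek_s, pd.DataFrame(), spoil, cfg)
    bundle.samples = generate_field_samples(bundle, cfg)
    return bundle


def _percentile_rank(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    ranks = np.empty(values.size, dtype=float)
    ranks[order] = np.arange(values.size)
    return ranks / max(values.size - 1, 1)


def _tek_maps(cfg: SynthConfig, meta: GridMeta, elev: np.ndarray,
              landcover: np.ndarray, dist_m: np.ndarray,
              spoil: np.ndarray) -> tuple[Grid, Grid]:
    """Three-class knowledge maps correlated with elevation and channels.

    Vulnerability: low-lying, water-adjacent marsh rates high (class 3);
    class probabilities are monotone in the elevation percentile. A strip
    of the marsh is left NODATA to emulate the smaller footprint of the
    vulnerability assessment. Sustainability: high marsh rates high, and
    spoil-bank cells are forced to the top class with probability 0.9.
    """
    rng = _rng(cfg.seed, "tek")
    wet = landcover == WETLAND
    nodata = int(NODATA)

    pct = np.zeros(meta.shape)
    pct[wet] = _percentile_rank(elev[wet])
    class_noise_v = _smooth_field(rng, meta.shape, 4.0)
    class_noise_s = _smooth_field(rng, meta.shape, 4.0)

    vuln_score = (0.55 * (1.0 - pct) + 0.30 * np.exp(-dist_m / 20.0)
                  + 0.15 * class_noise_v)
    sust_score = 0.70 * pct + 0.30 * class_noise_s

    def classify(score: np.ndarray) -> np.ndarray:
        q1, q2 = np.quantile(score[wet], [1.0 / 3.0, 2.0 / 3.0])
        cls = 1 + (score > q1).astype(int) + (score > q2).astype(int)
        return np.where(wet, cls, nodata)

    vuln = classify(vuln_score)
    sust = classify(sust_score)

    spoil_high = spoil & wet & (rng.random(meta.shape) < 0.9)
    sust[spoil_high] = 3

    # Smaller data footprint for the vulnerability layer: drop the eastern
    # 15% of the marsh from coverage.
    easting, _ = meta.cell_centers()
    if wet.any():
        cut = np.quantile(easting[wet], 0.85)
        vuln[wet & (easting > cut)] = nodata

    meta_cat = GridMeta(meta.n_rows, meta.n_cols, meta.cell_size,
                        meta.xll, meta.yll, nodata=float(nodata), crs=meta.crs)
    return Grid(vuln, meta_cat), Grid(sust, meta_cat)


# ---------------------------------------------------------------------------
# Field samples
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = [
    "site", "transect", "subsite", "replicate", "easting", "northing",
    "elevation_m", "ab_wet_g", "ab_dry_g", "bg_dry_g", "soil_wet_g",
    "soil_dry_g", "extract_salinity_ppt", "water_volume_L", "filter_mg",
    "filter_plus_solids_mg", "filter_plus_ash_mg",
]


def _pick_sites(bundle: SyntheticBundle) -> list[tuple[int, int]]:
    """Five wetland cells spread west-east in the lower (bayward) marsh.

    Sites sit on platform-like elevations (near ``platform_mean``) a few
    cells back from the water's edge, mirroring the field campaign.
    """
    cfg = bundle.config
    lc = np.asarray(bundle.landcover.data)
    dem = np.asarray(bundle.dem.data)
    wet = lc == WETLAND
    if wet.sum() < 5:
        raise ValueError("fewer than 5 candidate wetland sites")
    dist = ndimage.distance_transform_edt(lc != WATER)
    dist_m = dist * bundle.dem.meta.cell_size
    cand = (wet & (dist_m >= 6.0) & (dist_m <= 80.0)
            & (np.abs(dem - cfg.platform_mean) <= 0.15))
    if cand.sum() < 5:
        cand = wet & (dist_m >= 6.0) & (dist_m <= 80.0)
    if cand.sum() < 5:
        cand = wet
    rr, cc = np.nonzero(cand)
    edges = np.quantile(cc, np.linspace(0, 1, 6))
    # Spread target elevations across the platform band so the
    # biomass-elevation slope is identifiable from between-site contrast.
    z_targets = cfg.platform_mean + np.linspace(-0.1, 0.1, 5)
    sites: list[tuple[int, int]] = []
    for b in range(5):
        sel = (cc >= edges[b]) & (cc <= edges[b + 1])
        if not sel.any():
            sel = np.ones_like(cc, dtype=bool)
        rows_b, cols_b = rr[sel], cc[sel]
        j = int(np.argmin(np.abs(dem[rows_b, cols_b] - z_targets[b])))
        sites.append((int(rows_b[j]), int(cols_b[j])))
    return sites


def generate_field_samples(bundle: SyntheticBundle,
                           config: SynthConfig) -> pd.DataFrame:
    """Emit the 60-record nested field table with raw bench measurements.

    5 sites x 2 transects x 3 subsites x 2 replicates. Biomass follows
    ``intercept + slope * elevation`` plus a site effect and residual noise
    (truncated at zero); belowground biomass is ``bg_factor`` times the
    aboveground mean. Raw weights, volumes, and extract salinities are
    back-computed so the laboratory equations can be exercised end to end.
    """
    cfg = config
    rng = _rng(cfg.seed, "samples")
    meta = bundle.dem.meta
    dem = np.asarray(bundle.dem.data)
    easting, northing = meta.cell_centers()
    ref_north = float(northing.mean())

    sites = _pick_sites(bundle)
    ab_site = rng.normal(0.0, cfg.site_sd, len(sites))
    bg_site = rng.normal(0.0, cfg.site_sd * cfg.bg_factor, len(sites))
    tss_site = rng.normal(0.0, cfg.tss_site_sd, len(sites))

    records = []
    for i, (row, col) in enumerate(sites):
        site_e = float(easting[row, col])
        site_n = float(northing[row, col])
        z_site = float(dem[row, col])
        for transect in (1, 2):
            for subsite in (1, 2, 3):
                # transects 2 m apart, subsites 1 m apart along the transect
                e = site_e + (subsite - 2) * 1.0
                n = site_n - (transect - 1.5) * 2.0
                z = z_site + 0.005 * (subsite - 2) + rng.normal(0.0, 0.008)
                for replicate in (1, 2):
                    ab = max(0.0, cfg.biomass_intercept + cfg.biomass_slope * z
                             + ab_site[i] + rng.normal(0.0, cfg.residual_sd))
                    bg = max(0.0, cfg.bg_factor
                             * (cfg.biomass_intercept + cfg.biomass_slope * z)
                             + bg_site[i]
                             + rng.normal(0.0, cfg.residual_sd * cfg.bg_factor))
                    ab_dry = ab * QUADRAT_AREA_M2
                    bg_dry = bg * CORE_AREA_M2

                    porewater = max(0.5, cfg.porewater_mean_ppt
                                    + rng.normal(0.0, 1.5))
                    moisture_frac = float(np.clip(
                        0.55 + rng.normal(0.0, 0.03), 0.35, 0.75))
                    soil_wet = 10.0
                    soil_dry = soil_wet * (1.0 - moisture_frac)
                    extract_s = porewater * (soil_wet - soil_dry) / 20.0

                    tss = max(1.0, cfg.tss_mean
                              + cfg.tss_north_gradient * (n - ref_north)
                              + tss_site[i]
                              + rng.normal(0.0, cfg.tss_residual_sd))
                    volume = 0.5
                    filter_mg = 100.0 + rng.normal(0.0, 1.0)
                    filter_ash = filter_mg + tss * volume
                    filter_solids = filter_mg + (tss / _INORGANIC_FRACTION) * volume

                    records.append((i + 1, transect, subsite, replicate, e, n,
                                    z, ab_dry / _DRY_FRACTION, ab_dry, bg_dry,
                                    soil_wet, soil_dry, extract_s, volume,
                                    filter_mg, filter_solids, filter_ash))
    return pd.DataFrame.from_records(records, columns=SAMPLE_COLUMNS)


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as ESRI ASCII grids plus a samples CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "dem": write_grid(bundle.dem, outdir / "dem.asc"),
        "landcover": write_grid(bundle.landcover, outdir / "landcover.asc",
                                fmt="%d"),
        "tek_vulnerability": write_grid(bundle.tek_vulnerability,
                                        outdir / "tek_vulnerability.asc",
                                        fmt="%d"),
        "tek_sustainability": write_grid(bundle.tek_sustainability,
                                         outdir / "tek_sustainability.asc",
                                         fmt="%d"),
    }
    samples_path = outdir / "samples.csv"
    bundle.samples.to_csv(samples_path, index=False)
    paths["samples"] = samples_path
    return paths


def land_fraction(landcover: Grid) -> float:
    """Fraction of all cells that are wetland."""
    data = np.asarray(landcover.data)
    return float((data == WETLAND).sum() / data.size)
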