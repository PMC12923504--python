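# Methods

## Model

The simulator advances a raster marsh annually. Per wetland cell,

    z_t = z_{t-1} - RSLR_t + Acc_t - Ero_t,

with all terms in m/yr and elevation tracked relative to a fixed tidal
datum (sea level rises; MLW/MHW stay put). Open-water cells receive only
−RSLR. After the synchronous update, any wetland cell below MLW converts
to open water, permanently, and its loss year is recorded. The update is
order-independent by construction and is checked bit-for-bit against a
naive cell-by-cell reference implementation in the test suite.

### Accretion

    Acc = m_acc [ k_settle · TSS · H(z) · (1 + k_trap · min(B_ag/B_ref, 1)) / ρ_b
                  + k_org · B_bg ]

- `H(z)` — hydroperiod proxy: clamp((MHW − z)/(MHW − MLW), 0, 1). This
  stands in for a hydrodynamic submodel (out of scope here); it captures
  the first-order fact that lower marsh is flooded longer and therefore
  captures more sediment. It ignores wind-driven (meteorological)
  flooding, which dominates actual inundation in microtidal Louisiana.
- `TSS` — inorganic suspended solids, mg/L (numerically g/m³), from the
  fitted northing trend projected on the grid; static through time.
- Trapping — aboveground biomass increases capture efficiency up to a
  saturation at `B_ref`; bounded so accretion cannot run away.
- Organic term — linear in belowground biomass; the field's organic
  contributor without an asserted functional form.
- Biomass feedback — `B_ag`, `B_bg` are re-evaluated from the fitted
  linear biomass–elevation relation at the *current* elevation each year
  (truncated at 0), so productivity declines as a cell drowns. Static
  biomass rasters are also accepted.

### Erosion

    Ero = m_ero · e_base · (water 4-neighbours)/4     on wetland cells.

A vertical-rate proxy for edge retreat: fully exposed edges lose
`e_base` per year, interior marsh none. It cannot represent the fast
lateral wave-driven retreat of real bay shorelines; see Limitations.

## Parameters (units, defaults, why)

| parameter | default | units | rationale |
|---|---|---|---|
| MLW / MHW | −0.15 / +0.15 | m | ~0.3 m microtidal range centred on the datum |
| ρ_b | 0.289 | g/cm³ | monitoring-program bulk density for this estuary |
| k_settle | 60 | m/yr | effective capture velocity; with 30 mg/L TSS gives ~8 mm/yr inorganic accretion near MLW after calibration |
| k_trap / B_ref | 1.0 / 1000 | – / g/m² | doubles capture at reference aboveground biomass, then saturates |
| k_org | 4e-6 | m/yr per g/m² | ~5–9 mm/yr organic accretion over the platform's belowground biomass range |
| e_base | 0.02 | m/yr | edge retreat of order one cell per few decades at 2 m cells |
| calibration target | 0.008 | m/yr | feldspar-horizon-style accretion ≈ the current RSLR rate (9.1 mm/yr), i.e. a marsh near dynamic equilibrium today |

`calibrate_accretion` scales (k_settle, k_org) by one common factor so
mean accretion at the five field-site cells hits the target; accretion is
linear in the pair, so the match is exact.

With these choices the accretion capacity (its maximum over the
intertidal range, after calibration) is ~11–13 mm/yr: rates below it let
cells find an equilibrium elevation; rates above it make loss a matter of
transit time through the intertidal zone. That one number organizes all
of the scenario behaviour below.

## Empirical surfaces

Because the sampling is nested (replicates in subsites in transects in
five sites), responses are fitted with a random-intercept linear mixed
model. Two conventions, both deliberate:

- **REML estimates and standard errors, ML log-likelihood/AIC.** With
  only five groups, ML variance components are biased low and 2-SE
  intervals under-cover (measured 83/100 vs 90/100 for REML in the
  generator's parameter-recovery simulation). AIC must nevertheless come
  from ML fits to be comparable across fixed-effect sets. This mirrors
  the default behaviour of the standard mixed-model tooling in this
  field.
- **Optimizer hygiene.** The default statsmodels optimizer occasionally
  terminates on a degenerate boundary (infinite likelihood, garbage
  coefficients — observed at one generator seed). Fits are validated and
  polished across a default → Powell → BFGS cascade, keeping the best
  finite-likelihood solution, and rows are canonically sorted by group so
  estimates do not depend on table order.

Grid projection is population-level (random intercept 0), truncated at
zero. The shipped pipeline uses elevation-only biomass and northing-only
TSS structures; salinity- and easting-augmented candidates are fitted and
reported in the AIC table but do not drive the surfaces.

## Threshold search

The RSLR threshold for year Y is the constant rate whose remaining area
at Y is midway between the areas under the low anchor (current rate,
9.1 mm/yr) and the high anchor (20 mm/yr). Remaining area is monotone
non-increasing in rate, which is verified on a 5-point scan before
bisection (bracket tolerance 1e-4 m/yr); a non-monotone scan (degenerate
landscapes) falls back to a dense grid scan with linear interpolation and
flags the trace. Every candidate rate is simulated — no interpolation
between runs — and constant-rate runs are cached across target years.

## Synthetic world

The generator emulates the structure of the study system, not its
geography: a marsh platform at 0.40 ± 0.05 m (sites span 0.3–0.5 m), a
bay to the south, two sinuous channels with one-cell spoil-bank ridges
(high TEK sustainability with probability 0.9), a low-marsh fringe
grading from ~0.02 m at the water's edge to the platform over 24 m, a
0.20 m bayward tilt, smoothed (≈5-cell correlation length) elevation
noise, and an initial land fraction targeted at 46.2% by placing the bay
boundary. TEK vulnerability is high where marsh is low and channel-
adjacent, with a masked eastern strip emulating the smaller footprint of
that assessment. Field tables (5 × 2 × 3 × 2 = 60 records) carry raw
bench measurements (wet/dry weights, extract salinities, filter masses,
volumes) back-computed from the target quantities so the laboratory
equations are exercised end to end. One seed feeds named substreams
(dem / tek / samples), so every artifact is bit-reproducible.

Two deliberately structural choices:

- The continuous fringe-to-platform elevation spread makes remaining
  area decrease over the whole 9–20 mm/yr scan at every horizon, so
  thresholds exist and shrink with horizon (measured 10/10 seeds).
- `site_sd = 20 g/m²`: with five sites, slope SEs are honest only when
  between-site noise is small relative to the elevation contrast; this
  value reflects a world where elevation genuinely is the dominant
  biomass driver.

The "tuned" low-platform configuration used to examine mid-century
collapse (platform 0.15 m, tilt 0.05 m, 12 m fringe) puts platform
headroom (~0.30 m) where the high-acceleration ramp crosses the
accretion capacity shortly after 2050, concentrating loss in 2050–2075.

What a green test does *not* establish: agreement with the study's
absolute numbers (areas, thresholds in mm/yr, kappa/figure-of-merit
values), which depend on the unreleased rasters; realistic wind-driven
hydroperiod; spatial TSS dynamics; or vegetation community change.

## Validation statistics

The transition tally excludes cells that are NODATA in any of the three
maps. Kappa Simulation conditions on the initial class:
P0, PeT = Σ_o p(o) Σ_c p_ref(c|o)p_sim(c|o), PmaxT with min in place of
the product; K_transition = (PmaxT − PeT)/(1 − PeT), K_translocation =
(P0 − PeT)/(PmaxT − PeT), and their product. Zero-denominator cases are
reported as flagged fields (PeT = 1 → undefined; PmaxT = PeT with
P0 = PeT → K_translocation 1 by convention), never exceptions, so batch
sweeps do not abort. For the figure of merit, a reference change
simulated as a change to the *wrong* class counts as a miss (the
reference change was not correctly simulated); with binary maps the case
cannot arise. Both statistics are verified against an independent
brute-force enumeration on 1000 random map triples.

## Numerical conventions

- Rates are mm/yr in user-facing files and converted to m/yr exactly once
  at ingest; bulk density g/cm³ → g/m³ internally.
- Raster convention: row 0 north, cell centres carry coordinates,
  half-open extents; ESRI ASCII grids on disk.
- Conversion uses strict `z < MLW`; a cell landing exactly on MLW
  survives. Cells lost after the classification horizon count as
  persistent for vulnerability classing.
- The exact-fit path of the mixed model (zero residual variance) floors
  σ² at 1e-12 so the reported AIC stays finite.
- Cross-tab percentages are computed over valid-cell counts; on the
  uniform grids used here this equals area weighting, and areas are
  reported alongside.

## Known limitations

- The vertical edge-erosion proxy cannot reproduce knife-edge, laterally
  propagating shoreline collapse; consequently, on the default platform
  the low-acceleration ramp (to the 2100 threshold) still loses the
  low-marsh fringe by 2100 — more than a field system with near-threshold
  equilibrium dynamics would show.
- TSS is static in time and fitted on northing only.
- Thresholds near the upper anchor (20 mm/yr) compress the midway
  contrast at 2050 on resilient landscapes; the search reports the trace
  so such cases are auditable.
- The 2075 threshold reuses the 9.1/20 mm/yr anchors rather than
  year-specific anchors, matching the definition used throughout.
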