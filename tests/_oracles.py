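"""Independent reference implementations used as test oracles.

These deliberately avoid the production code paths: the simulator oracle
is a naive cell-by-cell triple loop in pure Python, and the validation
oracle counts contingencies with dictionaries and evaluates the agreement
formulas directly. They are slow and exist only to check the vectorized
engines.
"""

from __future__ import annotations

import numpy as np

from marshline.dynamics import WATER, WETLAND


def _biomass_at(spec, z: float, i: int, j: int) -> float:
    if isinstance(spec, tuple):
        intercept, slope = spec
        return max(intercept + slope * z, 0.0)
    return float(spec[i, j])


def reference_step(elevation, landcover, loss_year, year, params, rslr,
                   tss, ab_spec, bg_spec):
    """One naive annual step; mirrors the stated update rule cell by cell."""
    n_rows, n_cols = elevation.shape
    new_elev = np.empty_like(elevation)
    bd = params.bulk_density * 1.0e6
    for i in range(n_rows):
        for j in range(n_cols):
            z = elevation[i, j]
            if landcover[i, j] == WETLAND:
                ab = _biomass_at(ab_spec, z, i, j)
                bg = _biomass_at(bg_spec, z, i, j)
                frac = (params.mhw - z) / (params.mhw - params.mlw)
                h = min(max(frac, 0.0), 1.0)
                trap = 1.0 + params.k_trap * min(ab / params.b_ag_ref, 1.0)
                acc = params.acc_multiplier * (
                    params.k_settle * float(tss[i, j]) * h * trap / bd
                    + params.k_org * bg)
                n_water = 0
                for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < n_rows and 0 <= jj < n_cols \
                            and landcover[ii, jj] == WATER:
                        n_water += 1
                ero = params.ero_multiplier * params.e_base * (n_water / 4.0)
                new_elev[i, j] = z - rslr + (acc - ero)
            else:
                new_elev[i, j] = z - rslr + 0.0
    new_lc = landcover.copy()
    new_ly = loss_year.copy()
    for i in range(n_rows):
        for j in range(n_cols):
            if landcover[i, j] == WETLAND and new_elev[i, j] < params.mlw:
                new_lc[i, j] = WATER
                new_ly[i, j] = year + 1
    return new_elev, new_lc, new_ly


def reference_run(elevation, landcover, loss_year, start_year, n_years,
                  params, rslr, tss, ab_spec, bg_spec):
    """Run the naive reference for ``n_years`` at a constant rate."""
    elev, lc, ly = elevation.copy(), landcover.copy(), loss_year.copy()
    year = start_year
    for _ in range(n_years):
        elev, lc, ly = reference_step(elev, lc, ly, year, params, rslr,
                                      tss, ab_spec, bg_spec)
        year += 1
    return elev, lc, ly


# ---------------------------------------------------------------------------
# Validation statistics by direct enumeration
# ---------------------------------------------------------------------------

def brute_force_validation(initial, reference, simulated, nodata=-9999):
    """All agreement statistics from explicit per-cell enumeration."""
    triples = []
    it = np.nditer([initial, reference, simulated])
    for o, r, s in it:
        o, r, s = int(o), int(r), int(s)
        if nodata in (o, r, s):
            continue
        triples.append((o, r, s))
    n = len(triples)
    classes = sorted({v for tr in triples for v in tr})

    p0 = sum(1 for o, r, s in triples if r == s) / n
    pe = 0.0
    pmax = 0.0
    for o in classes:
        sub = [(r, s) for oo, r, s in triples if oo == o]
        if not sub:
            continue
        w = len(sub) / n
        for c in classes:
            p_ref = sum(1 for r, s in sub if r == c) / len(sub)
            p_sim = sum(1 for r, s in sub if s == c) / len(sub)
            pe += w * p_ref * p_sim
            pmax += w * min(p_ref, p_sim)

    hits = misses = false_alarms = persistence = 0
    for o, r, s in triples:
        ref_chg, sim_chg = r != o, s != o
        if ref_chg and sim_chg and r == s:
            hits += 1
        elif ref_chg:
            misses += 1
        elif sim_chg:
            false_alarms += 1
        else:
            persistence += 1
    denom = hits + misses + false_alarms
    fom = hits / denom if denom else 0.0

    out = {"p0": p0, "pe_transition": pe, "pmax_transition": pmax,
           "hits": hits, "misses": misses, "false_alarms": false_alarms,
           "correct_persistence": persistence, "figure_of_merit": fom,
           "total": n}
    if 1.0 - pe > 0:
        out["k_transition"] = (pmax - pe) / (1.0 - pe)
        if pmax - pe > 0:
            out["k_translocation"] = (p0 - pe) / (pmax - pe)
            out["k_simulation"] = out["k_transition"] * out["k_translocation"]
    return out
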