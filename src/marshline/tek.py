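"""Vulnerability classing of simulated loss and cross-tabulation against
traditional-ecological-knowledge (TEK) class maps.

The simulator's per-cell loss year is collapsed into the three-class
vulnerability scheme used throughout this analysis: cells lost by 2050 are
most vulnerable (3), cells lost after 2050 but by 2100 are medium (2), and
cells persistent at 2100 are least vulnerable (1). That model-derived map
is then cross-tabulated against the Tribe's vulnerability and
sustainability class rasters (values 1-3), optionally restricted to one
class of a masking layer — e.g. the distribution of model vulnerability
inside the top TEK sustainability areas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import NEVER_WETLAND, PERSISTENT
from .grid import Grid, GridMeta, require_aligned

TEK_CLASSES = (1, 2, 3)


def classify_vulnerability(loss_year: Grid, start_year: int,
                           end_year: int, y1: int = 2050,
                           y2: int = 2100) -> Grid:
    """Three-class vulnerability from a loss-year grid.

    loss_year <= y1 -> 3 (most vulnerable); y1 < loss_year <= y2 -> 2;
    persistent at y2 -> 1; cells that were never wetland -> NODATA.

    Raises ``ValueError`` if the run did not reach ``y2``.
    """
    if end_year < y2:
        raise ValueError(f"run horizon {end_year} is shorter than y2={y2}")
    if not (start_year < y1 < y2):
        raise ValueError("need start_year < y1 < y2")
    ly = np.asarray(loss_year.data).astype(int)
    nodata = int(loss_year.meta.nodata)
    out = np.full(ly.shape, nodata, dtype=int)
    wet0 = ly != NEVER_WETLAND
    lost = wet0 & (ly != PERSISTENT)
    out[wet0 & ~lost] = 1
    out[lost & (ly > y1) & (ly <= y2)] = 2
    out[lost & (ly <= y1)] = 3
    out[lost & (ly > y2)] = 1          # lost only after the horizon of interest
    return Grid(out, loss_year.meta)


@dataclass
class CrossTab:
    """Class-by-class percentages and areas between two class grids."""

    percentages: pd.DataFrame      # rows: secondary class; cols: primary class
    areas_ha: pd.DataFrame
    n_valid: int
    mask_description: str
    empty: bool = False


def crosstab(primary: Grid, secondary: Grid,
             mask_class: int | None = None) -> CrossTab:
    """Distribution of ``primary`` classes within each ``secondary`` class.

    Restricted to cells valid in both layers; if ``mask_class`` is given,
    further restricted to secondary cells of that class. Each nonempty row
    of the percentage table sums to 100. An empty intersection yields an
    empty, flagged table rather than an exception.
    """
    require_aligned(primary, secondary)
    p = np.asarray(primary.data).astype(int)
    s = np.asarray(secondary.data).astype(int)
    valid = (p != int(primary.meta.nodata)) & (s != int(secondary.meta.nodata))
    desc = "all valid cells"
    if mask_class is not None:
        valid &= s == mask_class
        desc = f"secondary class == {mask_class}"
    cell_ha = primary.meta.cell_area_m2 / 1.0e4
    if not valid.any():
        empty = pd.DataFrame(columns=list(TEK_CLASSES))
        return CrossTab(empty, empty.copy(), 0, desc, empty=True)

    rows = sorted(np.unique(s[valid]).tolist())
    cols = sorted(np.unique(p[valid]).tolist())
    counts = pd.DataFrame(0, index=rows, columns=cols, dtype=float)
    for r in rows:
        sel = valid & (s == r)
        vals, n = np.unique(p[sel], return_counts=True)
        counts.loc[r, vals] = n
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    areas = counts * cell_ha
    pct.index.name = areas.index.name = "secondary_class"
    pct.columns.name = areas.columns.name = "primary_class"
    return CrossTab(pct, areas, int(valid.sum()), desc)


def loss_area_by_class(loss_year: Grid, tek: Grid, start_year: int,
                       end_year: int,
                       years: "tuple[int, ...]" = (2050, 2075, 2100)
                       ) -> pd.DataFrame:
    """Hectares of simulated wetland loss per TEK class by milestone year.

    One row per TEK class with cumulative loss columns (``lost_by_YYYY``),
    the area persistent at the final milestone, and the class total; the
    persistent column plus the last milestone column equals the total.
    """
    require_aligned(loss_year, tek)
    if max(years) > end_year:
        raise ValueError(f"milestone {max(years)} beyond run horizon {end_year}")
    ly = np.asarray(loss_year.data).astype(int)
    tk = np.asarray(tek.data).astype(int)
    wet0 = ly != NEVER_WETLAND
    valid = wet0 & (tk != int(tek.meta.nodata))
    lost = valid & (ly != PERSISTENT)
    cell_ha = loss_year.meta.cell_area_m2 / 1.0e4
    final = max(years)
    records = []
    for cls in sorted(np.unique(tk[valid]).tolist()):
        in_cls = valid & (tk == cls)
        row = {"tek_class": cls}
        for y in sorted(years):
            row[f"lost_by_{y}"] = float((in_cls & lost & (ly <= y)).sum()
                                        * cell_ha)
        persistent = in_cls.sum() - (in_cls & lost & (ly <= final)).sum()
        row["persistent_ha"] = float(persistent * cell_ha)
        row["total_ha"] = float(in_cls.sum() * cell_ha)
        records.append(row)
    return pd.DataFrame.from_records(records)
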