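"""Three-map validation of simulated land-cover change.

Given an initial map, a reference final map (ground truth), and a
simulated final map, this module computes change-aware agreement
statistics. A traditional kappa is dominated by persistent cells; the
Kappa Simulation variant conditions on the initial class so only the
modelled *transitions* are scored:

    P0      = proportion of cells where reference and simulated finals agree
    PeT     = sum_o p(o) * sum_c p_ref(c|o) * p_sim(c|o)
    PmaxT   = sum_o p(o) * sum_c min(p_ref(c|o), p_sim(c|o))
    K_transition    = (PmaxT - PeT) / (1 - PeT)      (quantities of change)
    K_translocation = (P0 - PeT) / (PmaxT - PeT)     (locations of change)
    K_simulation    = K_transition * K_translocation = (P0 - PeT) / (1 - PeT)

The figure of merit scores only the changing cells:
hits / (hits + misses + false alarms), where a hit is a reference change
simulated as the same change, a miss is a reference change the simulation
got wrong (persistence or the wrong class), and a false alarm is simulated
change where the reference persisted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Grid, require_aligned


@dataclass
class TransitionTally:
    """Joint counts over (initial, reference-final, simulated-final) triples."""

    counts: np.ndarray              # (K, K, K) array
    classes: tuple                  # class values, NODATA excluded
    total: int

    def __post_init__(self) -> None:
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if int(self.counts.sum()) != self.total:
            raise ValueError("total does not match counts")


def tally(initial: Grid, reference_final: Grid,
          simulated_final: Grid) -> TransitionTally:
    """Exact joint counts over cells valid in all three maps.

    Cells carrying NODATA in *any* map are excluded symmetrically, so a
    layer with a smaller data footprint restricts the comparison to the
    common area.
    """
    require_aligned(initial, reference_final, simulated_final)
    grids = [initial, reference_final, simulated_final]
    arrays = [np.asarray(g.data) for g in grids]
    valid = np.ones(arrays[0].shape, dtype=bool)
    for g, a in zip(grids, arrays):
        valid &= a != g.meta.nodata
    vals = [a[valid] for a in arrays]
    classes = tuple(sorted(set(np.unique(np.concatenate(vals)).tolist())))
    index = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    idx = [np.vectorize(index.get, otypes=[int])(v) if v.size else
           np.zeros(0, dtype=int) for v in vals]
    counts = np.zeros((k, k, k), dtype=np.int64)
    np.add.at(counts, (idx[0], idx[1], idx[2]), 1)
    return TransitionTally(counts, classes, int(valid.sum()))


@dataclass
class ValidationReport:
    """All change-validation statistics from one tally."""

    p0: float
    pe_transition: float
    pmax_transition: float
    k_transition: float
    k_translocation: float
    k_simulation: float
    hits: int
    misses: int
    false_alarms: int
    correct_persistence: int
    figure_of_merit: float
    total: int
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "p0", "pe_transition", "pmax_transition", "k_transition",
            "k_translocation", "k_simulation", "hits", "misses",
            "false_alarms", "correct_persistence", "figure_of_merit",
            "total", "flags")}


def _change_counts(t: TransitionTally) -> tuple[int, int, int, int]:
    """(hits, misses, false_alarms, correct_persistence) from a tally."""
    hits = misses = false_alarms = persistence = 0
    k = len(t.classes)
    for o in range(k):
        for r in range(k):
            for s in range(k):
                n = int(t.counts[o, r, s])
                if n == 0:
                    continue
                ref_changed = r != o
                sim_changed = s != o
                if ref_changed and sim_changed and r == s:
                    hits += n
                elif ref_changed:          # wrong class or persistence
                    misses += n
                elif sim_changed:          # reference persisted
                    false_alarms += n
                else:
                    persistence += n
    return hits, misses, false_alarms, persistence


def figure_of_merit(t: TransitionTally) -> tuple[float, bool]:
    """FoM = hits / (hits + misses + false alarms); (value, degenerate flag).

    Defined as 0 (flagged) when no cell changes in either map.
    """
    hits, misses, false_alarms, _ = _change_counts(t)
    denom = hits + misses + false_alarms
    if denom == 0:
        return 0.0, True
    return hits / denom, False


def kappa_simulation(t: TransitionTally) -> ValidationReport:
    """Full validation report: Kappa Simulation components plus FoM."""
    flags: list[str] = []
    if t.total == 0:
        raise ValueError("empty tally: no valid cells")
    c = t.counts.astype(float)
    total = float(t.total)
    p_o = c.sum(axis=(1, 2)) / total                 # initial-class marginals
    ref_o = c.sum(axis=2)                            # (o, r) counts
    sim_o = c.sum(axis=1)                            # (o, s) counts

    p0 = float(np.einsum("occ->", c) / total)        # ref final == sim final
    pe_t = 0.0
    pmax_t = 0.0
    for o in range(len(t.classes)):
        n_o = ref_o[o].sum()
        if n_o == 0:
            continue
        p_ref = ref_o[o] / n_o
        p_sim = sim_o[o] / n_o
        pe_t += p_o[o] * float(np.dot(p_ref, p_sim))
        pmax_t += p_o[o] * float(np.minimum(p_ref, p_sim).sum())

    if 1.0 - pe_t <= 0.0:
        flags.append("degenerate: PeT = 1, kappa undefined")
        k_tr = k_tl = k_sim = float("nan")
    else:
        k_tr = (pmax_t - pe_t) / (1.0 - pe_t)
        if pmax_t - pe_t == 0.0:
            if p0 == pe_t:
                k_tl = 1.0
                flags.append("PmaxT = PeT with P0 = PeT: "
                             "K_translocation set to 1 by convention")
            else:
                k_tl = float("nan")
                flags.append("PmaxT = PeT with P0 != PeT: "
                             "K_translocation undefined")
        else:
            k_tl = (p0 - pe_t) / (pmax_t - pe_t)
        k_sim = k_tr * k_tl

    hits, misses, false_alarms, persistence = _change_counts(t)
    fom, fom_flag = figure_of_merit(t)
    if fom_flag:
        flags.append("no change in reference or simulation: FoM set to 0")
    return ValidationReport(p0, pe_t, pmax_t, float(k_tr), float(k_tl),
                            float(k_sim), hits, misses, false_alarms,
                            persistence, fom, t.total, flags)


def validate_maps(initial: Grid, reference_final: Grid,
                  simulated_final: Grid) -> ValidationReport:
    """Convenience wrapper: tally three maps and report all statistics."""
    return kappa_simulation(tally(initial, reference_final, simulated_final))
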