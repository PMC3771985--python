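"""Crypt performance measures, labelling-index and clonal statistics.

The crypt is judged as a "mature-cell factory" on four measures, each also
reported normalised by its target value:

* total cell number maintained at steady state (target: 704, the capacity
  of the descending-colon crypt);
* cell production rate, the number of cells leaving the orifice per hour;
* mature-cell proportion (target: 504/704, from the 200 proliferative
  cells reported experimentally);
* mature-cell order, the mean over mature cells of the fraction of each
  cell's contact neighbours that are also mature.  Near 1 for a perfectly
  segregated mature compartment; strictly below 1 in any healthy crypt
  because proliferative and mature cells always touch somewhere.

Also implemented here: the labelling-index (LI) protocol (mark all S-phase
cells, chase, report the labelled fraction per crypt row) and clonal
ribbon statistics (mark basal clones, count gaps in their vertical bands).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import RunResult, Simulation
from .geometry import CryptGeometry, find_contacts, row_index
from .state import PHASE_S, CryptState

__all__ = ["MeasureTargets", "PerformanceMeasures", "cell_order",
           "mature_cell_order", "performance_summary",
           "summarize_replicates", "label_s_phase", "li_profile",
           "simulate_li", "LIProfile", "mark_clones",
           "ribbon_gap_statistic", "column_index"]


@dataclass(frozen=True)
class MeasureTargets:
    """Normalisation targets for the four performance measures.

    ``production_rate`` has no directly printed target; the default 14
    cells/h follows from complete renewal of a 704-cell crypt in about two
    days, the reported epithelial turnover time in mice.
    """

    n_cells: float = 704.0
    proliferative_cells: float = 200.0
    production_rate: float = 14.0
    mature_order: float = 0.90

    @property
    def mature_proportion(self) -> float:
        return (self.n_cells - self.proliferative_cells) / self.n_cells


@dataclass
class PerformanceMeasures:
    n_cells: float
    production_rate: float
    mature_proportion: float
    mature_order: float
    n_proliferative: float
    steady_onset_h: float | None
    reached_steady: bool
    normalised: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {"n_cells": self.n_cells,
             "production_rate": self.production_rate,
             "mature_proportion": self.mature_proportion,
             "mature_order": self.mature_order,
             "n_proliferative": self.n_proliferative,
             "steady_onset_h": self.steady_onset_h,
             "reached_steady": self.reached_steady}
        d.update({f"norm_{k}": v for k, v in self.normalised.items()})
        return d


def cell_order(is_mature: np.ndarray, pairs) -> np.ndarray:
    """Per-cell order: fraction of contact neighbours that are mature.

    ``pairs`` is the (i, j) contact list at zero reach.  A cell with no
    neighbours has order 1 by convention.  Defined for every cell; the
    crypt statistic averages it over mature cells only.
    """
    n = is_mature.size
    i, j = pairs
    neighbours = (np.bincount(i, minlength=n)
                  + np.bincount(j, minlength=n)).astype(float)
    mature_nb = (np.bincount(i, weights=is_mature[j].astype(float),
                             minlength=n)
                 + np.bincount(j, weights=is_mature[i].astype(float),
                               minlength=n))
    with np.errstate(invalid="ignore", divide="ignore"):
        order = np.where(neighbours > 0, mature_nb / neighbours, 1.0)
    return order


def mature_cell_order(state: CryptState,
                      geometry: CryptGeometry) -> float:
    """Mean cell order over all mature cells; NaN if none are mature."""
    mature = state.mature
    if not mature.any():
        return float("nan")
    pairs = find_contacts(state.x, state.y, state.r, geometry, reach=0.0)
    return float(cell_order(mature, pairs)[mature].mean())


def performance_summary(result: RunResult,
                        targets: MeasureTargets = MeasureTargets(),
                        ) -> PerformanceMeasures:
    """Time-averaged performance of one run over its measurement window.

    Counts and the production rate are averaged over the (>= 3 day)
    post-steady-state window; the order statistic is averaged over the
    snapshots recorded in that window.  A run that never reached steady
    state is returned flagged with NaN measures so replicate aggregation
    can exclude it.
    """
    m = result.measurement_mask
    if not result.reached_steady or not m.any():
        return PerformanceMeasures(
            n_cells=float("nan"), production_rate=float("nan"),
            mature_proportion=float("nan"), mature_order=float("nan"),
            n_proliferative=float("nan"),
            steady_onset_h=result.steady_onset_h, reached_steady=False)
    n_cells = float(result.n_total[m].mean())
    production = float(result.exits_per_h[m].sum() / m.sum()
                       * (1.0 / result.config.sample_interval_h))
    mature_prop = float((result.n_mature[m] / result.n_total[m]).mean())
    orders = [mature_cell_order(s, result.config.geometry)
              for t, s in result.snapshots
              if result.steady_onset_h is not None
              and t > result.steady_onset_h]
    order = float(np.nanmean(orders)) if orders else float("nan")
    pm = PerformanceMeasures(
        n_cells=n_cells, production_rate=production,
        mature_proportion=mature_prop, mature_order=order,
        n_proliferative=float(result.n_proliferative[m].mean()),
        steady_onset_h=result.steady_onset_h, reached_steady=True)
    pm.normalised = {
        "n_cells": n_cells / targets.n_cells,
        "production_rate": production / targets.production_rate,
        "mature_proportion": mature_prop / targets.mature_proportion,
        "mature_order": order / targets.mature_order,
    }
    return pm


def summarize_replicates(measures: list[PerformanceMeasures]) -> dict:
    """Mean and variance of each measure across replicate runs.

    Runs that never reached steady state are excluded (and counted).
    """
    ok = [p for p in measures if p.reached_steady]
    out = {"replicates": len(measures), "completed": len(ok)}
    keys = ["n_cells", "production_rate", "mature_proportion",
            "mature_order", "n_proliferative"]
    def _stats(vals: np.ndarray) -> tuple[float, float]:
        vals = vals[~np.isnan(vals)]
        mean = float(vals.mean()) if vals.size else float("nan")
        var = float(vals.var(ddof=1)) if vals.size > 1 else float("nan")
        return mean, var

    for k in keys:
        mean, var = _stats(np.array([getattr(p, k) for p in ok],
                                    dtype=float))
        out[f"{k}_mean"] = mean
        out[f"{k}_var"] = var
    for k in (ok[0].normalised if ok else {}):
        mean, _ = _stats(np.array([p.normalised[k] for p in ok],
                                  dtype=float))
        out[f"norm_{k}_mean"] = mean
    return out


# ---------------------------------------------------------------------------
# Labelling index


@dataclass
class LIProfile:
    """Per-row labelled proportions (NaN where a row holds no cells)."""

    proportion: np.ndarray            # one value per crypt row
    mean: np.ndarray | None = None    # across replicates
    sd: np.ndarray | None = None


def label_s_phase(state: CryptState) -> int:
    """Mark every cell currently in S phase; returns the number marked."""
    in_s = state.phase == PHASE_S
    state.li_label |= in_s
    return int(in_s.sum())


def li_profile(state: CryptState, geometry: CryptGeometry) -> np.ndarray:
    """Labelled fraction of cells in each crypt row (cell centres binned).

    Rows containing no cells are reported as NaN, not zero.
    """
    rows = row_index(state.y, geometry)
    total = np.bincount(rows, minlength=geometry.n_length).astype(float)
    labelled = np.bincount(rows, weights=state.li_label.astype(float),
                           minlength=geometry.n_length)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = labelled / total
    prop[total == 0] = np.nan
    return prop


def simulate_li(sim: Simulation, chase_h: float = 1.0) -> LIProfile:
    """Run the labelling-index protocol on a crypt at steady state.

    All S-phase cells are marked; the label is inherited at division and
    never cleared (cells may carry it out of the crypt).  After
    ``chase_h`` simulated hours, the labelled proportion per crypt row is
    computed from cell centres.
    """
    label_s_phase(sim.state)
    hours = int(round(chase_h / sim.cfg.sample_interval_h))
    for _ in range(hours):
        sim.advance_sample()
    return LIProfile(li_profile(sim.state, sim.cfg.geometry))


# ---------------------------------------------------------------------------
# Clonal trajectories


def column_index(x, geometry: CryptGeometry):
    """0-based lateral column of a cell centre (analogue of row_index)."""
    w = geometry.width / geometry.n_circumference
    idx = np.floor(np.mod(np.asarray(x), geometry.width) / w).astype(int)
    return np.clip(idx, 0, geometry.n_circumference - 1)


def mark_clones(state: CryptState, n_clones: int,
                rng: np.random.Generator,
                geometry: CryptGeometry) -> None:
    """Label ``n_clones`` distinct cells at the crypt base.

    Clone identifiers are heritable (copied to daughters at division).
    Candidates are the cells of the bottom row; raises if fewer exist
    than clones requested.
    """
    base = np.flatnonzero(row_index(state.y, geometry) == 0)
    if n_clones > base.size:
        raise ValueError(
            f"requested {n_clones} clones but only {base.size} base cells")
    chosen = rng.choice(base, size=n_clones, replace=False)
    state.clone[chosen] = np.arange(n_clones, dtype=np.int32)


def ribbon_gap_statistic(state: CryptState,
                         geometry: CryptGeometry) -> dict[int, int]:
    """Gaps per clone: unlabelled cells vertically interposed in a ribbon.

    For each clone and each lateral column the clone occupies, cells of
    that column are ordered by height and every unmarked cell lying
    strictly between two cells of the clone counts as one gap.  Straight
    uninterrupted ribbons therefore score 0.
    """
    cols = column_index(state.x, geometry)
    gaps: dict[int, int] = {}
    for clone in np.unique(state.clone[state.clone >= 0]):
        count = 0
        member = state.clone == clone
        for c in np.unique(cols[member]):
            in_col = cols == c
            y_members = state.y[in_col & member]
            lo, hi = y_members.min(), y_members.max()
            strangers = in_col & ~member
            count += int(((state.y[strangers] > lo)
                          & (state.y[strangers] < hi)).sum())
        gaps[int(clone)] = count
    return gaps
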