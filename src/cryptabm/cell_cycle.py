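"""Spatially extended Smith-Martin cell cycle with explicit growth.

Proliferative cells follow a two-phase cycle: a stochastic phase A
(identified with G1) that a cell leaves with constant probability per unit
time, giving an exponentially distributed G1 duration, followed by a
deterministic phase B consisting of S, G2 and M with fixed durations.
Completing M triggers division into two equal-area daughters.

Cells grow in area at a constant rate during G1 and G2 chosen so that an
average cell doubles its area over an average G1 + G2, i.e. the daughter of
a mean-radius mother returns to mean radius.  Because G1 durations are
random, cell sizes vary; a minimum radius bars undersized cells from
leaving G1 and a maximum radius caps growth.

Default phase durations (hours) for the murine descending colon:

==========  =====  ====
phase       stem   TA
==========  =====  ====
G1 (mean)   22.5   7.0
S           20.0   6.2
G2           6.0   1.8
M            1.5   0.5
==========  =====  ====
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .state import (CLASS_STEM, PHASE_A, PHASE_G0, PHASE_G2, PHASE_M,
                    PHASE_S, CryptState)

__all__ = ["CellCycleParams", "TA_CYCLE", "STEM_CYCLE", "CycleConfig",
           "advance_cycle", "grow", "divide_cells",
           "sample_phase_a_durations", "random_cycle_position",
           "time_averaged_area_factor", "reference_packing_radius"]


@dataclass(frozen=True)
class CellCycleParams:
    """Smith-Martin phase durations (hours) for one proliferative class."""

    g1_mean: float
    s: float
    g2: float
    m: float

    def __post_init__(self) -> None:
        if min(self.g1_mean, self.s, self.g2, self.m) <= 0:
            raise ValueError("all phase durations must be positive")

    @property
    def phase_b(self) -> float:
        """Deterministic phase-B duration S + G2 + M."""
        return self.s + self.g2 + self.m

    @property
    def mean_cycle(self) -> float:
        return self.g1_mean + self.phase_b

    def scaled_g1(self, factor: float) -> "CellCycleParams":
        return CellCycleParams(self.g1_mean * factor, self.s, self.g2, self.m)


TA_CYCLE = CellCycleParams(g1_mean=7.0, s=6.2, g2=1.8, m=0.5)
STEM_CYCLE = CellCycleParams(g1_mean=22.5, s=20.0, g2=6.0, m=1.5)


@dataclass(frozen=True)
class CycleConfig:
    """Cycle parameters for both cell classes plus the size gates.

    ``r_min`` bars a cell from leaving G1 until it has grown past it (the
    short G2 then lifts it clearly above the minimum); ``r_max`` caps
    growth.  ``deterministic`` removes all stochasticity from phase A (the
    adapted pedigree variant): every cell spends exactly ``g1_mean`` in G1.
    """

    ta: CellCycleParams = TA_CYCLE
    stem: CellCycleParams = STEM_CYCLE
    mean_radius: float = 5.0
    r_min: float = 6.5
    r_max: float = 7.5
    deterministic: bool = False

    def params_for(self, cell_class: int) -> CellCycleParams:
        return self.stem if cell_class == CLASS_STEM else self.ta

    def growth_rate(self, cell_class: int) -> float:
        """Area growth rate (um^2/h): birth area doubled over mean G1+G2."""
        p = self.params_for(cell_class)
        birth_area = np.pi * self.mean_radius ** 2
        return birth_area / (p.g1_mean + p.g2)


def _per_class(cfg: CycleConfig, attr: str, cell_class: np.ndarray) -> np.ndarray:
    stem_v = getattr(cfg.stem, attr)
    ta_v = getattr(cfg.ta, attr)
    return np.where(cell_class == CLASS_STEM, stem_v, ta_v)


def grow(state: CryptState, cfg: CycleConfig, dt_h: float) -> None:
    """Advance growth of proliferative cells in G1 or G2 by ``dt_h`` hours.

    Growth is linear in area and clamped at ``r_max``; mature (G0) cells
    and cells in S or M do not grow.  Modifies ``state.r`` in place.
    """
    growing = (state.phase == PHASE_A) | (state.phase == PHASE_G2)
    if not growing.any():
        return
    idx = np.flatnonzero(growing)
    cls = state.cell_class[idx]
    rate = np.where(cls == CLASS_STEM, cfg.growth_rate(CLASS_STEM),
                    cfg.growth_rate(1))
    area = np.pi * state.r[idx] ** 2 + rate * dt_h
    state.r[idx] = np.minimum(np.sqrt(area / np.pi), cfg.r_max)


def advance_cycle(state: CryptState, cfg: CycleConfig, dt_h: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Advance cycle phases of all cells by one step of ``dt_h`` hours.

    Phase A is left stochastically with per-step probability
    ``1 - exp(-dt/g1_mean)`` (exactly exponential, so results are invariant
    to sub-dividing the step), gated on ``r >= r_min``; S, G2 and M elapse
    deterministically, with the overshoot past each boundary carried into
    the next phase.  Returns the indices of cells that completed M this
    step (the division flag); the caller performs the divisions.
    """
    if dt_h <= 0:
        raise ValueError("dt must be positive")
    cycling = state.phase != PHASE_G0
    state.clock[cycling] += dt_h

    # phase A -> S
    in_a = state.phase == PHASE_A
    if in_a.any():
        idx = np.flatnonzero(in_a)
        if cfg.deterministic:
            g1 = _per_class(cfg, "g1_mean", state.cell_class[idx])
            leave = state.clock[idx] >= g1
            overshoot = state.clock[idx] - g1
        else:
            g1 = _per_class(cfg, "g1_mean", state.cell_class[idx])
            p = 1.0 - np.exp(-dt_h / g1)
            leave = rng.random(idx.size) < p
            overshoot = np.zeros(idx.size)
        leave &= state.r[idx] >= cfg.r_min  # minimum-size gate
        moved = idx[leave]
        state.phase[moved] = PHASE_S
        state.clock[moved] = overshoot[leave] if cfg.deterministic else 0.0

    # deterministic B-phase bookkeeping: S -> G2 -> M -> divide
    for phase, nxt, attr in ((PHASE_S, PHASE_G2, "s"),
                             (PHASE_G2, PHASE_M, "g2")):
        mask = state.phase == phase
        if mask.any():
            idx = np.flatnonzero(mask)
            dur = _per_class(cfg, attr, state.cell_class[idx])
            done = state.clock[idx] >= dur
            moved = idx[done]
            state.clock[moved] -= dur[done]
            state.phase[moved] = nxt

    in_m = state.phase == PHASE_M
    dividers = np.empty(0, dtype=np.intp)
    if in_m.any():
        idx = np.flatnonzero(in_m)
        dur = _per_class(cfg, "m", state.cell_class[idx])
        dividers = idx[state.clock[idx] >= dur]
    return dividers


def divide_cells(state: CryptState, dividers: np.ndarray,
                 vertical_only: bool, rng: np.random.Generator,
                 ) -> tuple[CryptState, np.ndarray]:
    """Split each flagged mother into two equal-area daughters.

    Each daughter receives half the mother's area (radius ``r_m / sqrt 2``)
    and the daughters are placed symmetrically about the mother's centre
    along the division axis, separated so they just touch.  The axis is
    vertical when ``vertical_only`` else a uniformly random direction.
    Daughters start in phase A with clock 0 and inherit the mother's class,
    generation and labels; lineage typing (asymmetric stem division, TA
    generation increments, maturation at birth) is applied afterwards by
    the lineage rules.

    Returns the new state (mothers replaced by daughter pairs appended at
    the end) and the indices of the 2*k daughter cells within it.
    """
    k = len(dividers)
    if k == 0:
        return state, np.empty(0, dtype=np.intp)
    if (state.phase[dividers] == PHASE_G0).any():
        raise ValueError("mature cells never divide")
    mothers = state.take(dividers)
    r_d = mothers.r / np.sqrt(2.0)
    if vertical_only:
        ux, uy = np.zeros(k), np.ones(k)
    else:
        theta = rng.uniform(0.0, 2.0 * np.pi, size=k)
        ux, uy = np.cos(theta), np.sin(theta)

    daughters = CryptState.empty(2 * k)
    for name in ("r", "cell_class", "generation", "li_label", "clone",
                 "anchor_x"):
        arr = getattr(mothers, name)
        getattr(daughters, name)[:] = np.repeat(arr, 2)
    daughters.r[:] = np.repeat(r_d, 2)
    sign = np.tile([1.0, -1.0], k)
    daughters.x[:] = np.repeat(mothers.x, 2) + sign * np.repeat(r_d * ux, 2)
    daughters.y[:] = np.maximum(
        np.repeat(mothers.y, 2) + sign * np.repeat(r_d * uy, 2), 0.0)
    daughters.phase[:] = PHASE_A
    daughters.clock[:] = 0.0

    keep = np.ones(state.n, dtype=bool)
    keep[dividers] = False
    new_state = state.take(keep).append(daughters)
    daughter_idx = np.arange(new_state.n - 2 * k, new_state.n)
    return new_state, daughter_idx


def sample_phase_a_durations(n: int, params: CellCycleParams, dt_h: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo phase-A durations for ``n`` independent cells.

    Steps each cell through phase A with the per-step exit probability
    ``1 - exp(-dt/g1_mean)`` (no size gate) and returns the exit times in
    hours.  The sample mean converges to ``g1_mean + dt/2`` (mid-step
    correction), i.e. to ``g1_mean`` as ``dt -> 0``.
    """
    p = 1.0 - np.exp(-dt_h / params.g1_mean)
    steps = np.zeros(n, dtype=np.int64)
    active = np.arange(n)
    k = 0
    while active.size:
        k += 1
        exit_now = rng.random(active.size) < p
        steps[active[exit_now]] = k
        active = active[~exit_now]
    return steps * dt_h


def time_averaged_area_factor(params: CellCycleParams) -> float:
    """Mean area of a cycling cell over one cycle, in units of birth area.

    A cell is born with area ``A0``, grows linearly to ``2 A0`` over G1 and
    G2 (holding constant through S and M) and divides.  Time-averaging the
    resulting piecewise-linear trajectory over a cycle of mean length
    ``g1 + s + g2 + m`` (treating G1 at its mean duration) gives the
    average size of a proliferative cell, which exceeds the birth size.
    """
    g1, s, g2, m = params.g1_mean, params.s, params.g2, params.m
    a = g1 / (g1 + g2)          # area gained during G1, units of A0
    mean = (g1 * (1 + a / 2)    # G1: A0 -> (1+a) A0
            + s * (1 + a)       # S: constant
            + g2 * (3 + a) / 2  # G2: (1+a) A0 -> 2 A0
            + m * 2.0)          # M: constant at 2 A0
    return mean / params.mean_cycle


def reference_packing_radius(cycle: "CycleConfig | None" = None,
                             n_total: int = 704,
                             n_proliferative: int = 200) -> float:
    """Population-average cell radius for the crypt sheet fine-tuning.

    The sheet is sized so that exactly ``n_circumference * n_length``
    *average* cells tile it at the equilibrium overlap.  Because cycling
    cells are on average ~1.6x their birth area, the average cell of the
    reference crypt composition (704 cells of which 200 are proliferative,
    with TA-cell cycle timing) is larger than a newborn.  Returns the
    number-weighted mean radius of that reference population.
    """
    cycle = cycle if cycle is not None else CycleConfig()
    r0 = cycle.mean_radius
    r_cycling = r0 * np.sqrt(time_averaged_area_factor(cycle.ta))
    n_mature = n_total - n_proliferative
    return float((n_mature * r0 + n_proliferative * r_cycling) / n_total)


def random_cycle_position(n: int, params: CellCycleParams,
                          rng: np.random.Generator,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Unsynchronised initial phases: uniform position within a mean cycle.

    Draws a uniform point in ``[0, mean_cycle)`` per cell and converts it
    to (phase, clock), using ``g1_mean`` as the nominal phase-A length.
    Used to initialise the founding row of cells out of phase.
    """
    u = rng.uniform(0.0, params.mean_cycle, size=n)
    phase = np.empty(n, dtype=np.int8)
    clock = np.empty(n)
    bounds = np.array([params.g1_mean, params.s, params.g2, params.m])
    edges = np.concatenate([[0.0], np.cumsum(bounds)])
    codes = [PHASE_A, PHASE_S, PHASE_G2, PHASE_M]
    for lo, hi, code in zip(edges[:-1], edges[1:], codes):
        mask = (u >= lo) & (u < hi)
        phase[mask] = code
        clock[mask] = u[mask] - lo
    return phase, clock
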