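"""Cell-fate rules: pedigree hierarchy, niche maturation, adapted variants.

Two contrasting concepts of crypt organisation are encoded:

*Pedigree* -- a preprogrammed differentiation hierarchy.  Immortal stem
cells divide asymmetrically into one stem cell and one first-generation
transit-amplifying (TA) cell; TA cells divide symmetrically, incrementing
their generation, and the daughters of the final TA generation (default 5)
are mature.  Position plays no role in fate.

*Niche* -- fate is dictated by position.  All divisions are symmetric and
any cell inside the proliferative region (the basal fraction
``proliferation_region`` of the crypt) keeps cycling.  Maturation follows
one of two schemes: under ``only_new_cells_mature`` only daughters *born*
above the boundary mature, while cells that migrate out mid-cycle keep
cycling; otherwise any cell still in G1 whose centre crosses the boundary
matures immediately (cells already past G1, i.e. in S/G2/M, finish their
cycle).  Maturation is irreversible.

The adapted variants soften each model toward the other: the adapted
pedigree removes all cell-cycle stochasticity (see
:class:`~cryptabm.cell_cycle.CycleConfig`); the adapted niche replaces the
sharp boundary with a position-dependent maturation probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CryptGeometry
from .state import (CLASS_STEM, CLASS_TA, PHASE_A, PHASE_G0, CryptState)

__all__ = ["PEDIGREE", "NICHE", "LineageConfig", "pedigree_fate_daughters",
           "niche_mature_at_birth", "niche_mature_in_place",
           "position_maturation_probability"]

PEDIGREE = "pedigree"
NICHE = "niche"


@dataclass(frozen=True)
class LineageConfig:
    """Which organisational concept governs cell fate, and its knobs."""

    model: str = NICHE
    n_ta_generations: int = 5
    proliferation_region: float = 0.3
    only_new_cells_mature: bool = False
    deterministic_cycle: bool = False   # adapted pedigree
    position_pdf: bool = False          # adapted niche
    pdf_half_width: float = 0.15        # ramp half-width, fraction of height

    def __post_init__(self) -> None:
        if self.model not in (PEDIGREE, NICHE):
            raise ValueError(f"unknown model {self.model!r}")
        if not 0 < self.proliferation_region <= 1:
            raise ValueError("proliferation_region must be in (0, 1]")
        if self.n_ta_generations < 1:
            raise ValueError("n_ta_generations must be >= 1")


def pedigree_fate_daughters(state: CryptState, daughter_idx: np.ndarray,
                            cfg: LineageConfig) -> None:
    """Assign classes/generations to freshly created daughter pairs.

    Daughters arrive carrying their mother's class and generation (pairs
    are consecutive in ``daughter_idx``).  Stem mothers divide
    asymmetrically: the first daughter of the pair remains a stem cell
    (keeping the basal anchor), the second becomes a TA cell of
    generation 1.  TA mothers of generation ``g < n`` yield two TA cells
    of generation ``g + 1``; generation-``n`` mothers yield two mature
    (G0) cells.  Mature cells never divide, so a G0 mother is a contract
    violation.
    """
    if daughter_idx.size == 0:
        return
    first = daughter_idx[0::2]
    second = daughter_idx[1::2]
    stem_pairs = state.cell_class[first] == CLASS_STEM
    # asymmetric stem division: first stays stem, second becomes TA1
    ta_child = second[stem_pairs]
    state.cell_class[ta_child] = CLASS_TA
    state.generation[ta_child] = 1
    state.anchor_x[ta_child] = np.nan
    # symmetric TA division: both daughters advance a generation
    for half in (first, second):
        ta = half[state.cell_class[half] == CLASS_TA]
        was_stem_child = np.isin(ta, ta_child)
        bump = ta[~was_stem_child]
        state.generation[bump] += 1
        done = bump[state.generation[bump] > cfg.n_ta_generations]
        state.phase[done] = PHASE_G0
        state.generation[done] = cfg.n_ta_generations
        state.clock[done] = 0.0


def _boundary(cfg: LineageConfig, geometry: CryptGeometry) -> float:
    return cfg.proliferation_region * geometry.height


def niche_mature_at_birth(state: CryptState, daughter_idx: np.ndarray,
                          cfg: LineageConfig, geometry: CryptGeometry,
                          rng: np.random.Generator) -> None:
    """Maturation decision for newborn niche cells.

    With the sharp boundary, daughters whose centres lie above the
    proliferative region become mature.  The adapted niche variant instead
    draws maturity from the position-dependent probability ramp.
    """
    if daughter_idx.size == 0:
        return
    y = state.y[daughter_idx]
    if cfg.position_pdf:
        p = position_maturation_probability(y, cfg, geometry)
        mature = rng.random(daughter_idx.size) < p
    else:
        mature = y >= _boundary(cfg, geometry)
    idx = daughter_idx[mature]
    state.phase[idx] = PHASE_G0
    state.clock[idx] = 0.0


def niche_mature_in_place(state: CryptState, cfg: LineageConfig,
                          geometry: CryptGeometry,
                          rng: np.random.Generator) -> None:
    """Per-step maturation of G1 cells that left the proliferative region.

    Applies only when ``only_new_cells_mature`` is False: any cell still
    in phase A (G1) whose centre sits above the boundary matures
    immediately.  Cells in S, G2 or M finish their cycle; their daughters
    are then caught by the birth rule.  No-op for the adapted (PDF)
    variant, whose decisions are made at birth only so the maturation
    rate stays step-size independent.
    """
    if cfg.only_new_cells_mature or cfg.position_pdf:
        return
    out = (state.phase == PHASE_A) & (state.y >= _boundary(cfg, geometry))
    state.phase[out] = PHASE_G0
    state.clock[out] = 0.0


def position_maturation_probability(y, cfg: LineageConfig,
                                    geometry: CryptGeometry):
    """Maturation probability of the adapted niche model at height ``y``.

    A linear ramp centred on the proliferation boundary with half-width
    ``pdf_half_width * height``, clipped to [0, 1]: zero deep in the
    niche, one well above the boundary, one half exactly at it.
    """
    y = np.asarray(y, dtype=float)
    centre = _boundary(cfg, geometry)
    half = cfg.pdf_half_width * geometry.height
    return np.clip(0.5 + (y - centre) / (2.0 * half), 0.0, 1.0)
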