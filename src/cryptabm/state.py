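"""Struct-of-arrays container for the cell population of one crypt."""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

__all__ = ["PHASE_A", "PHASE_S", "PHASE_G2", "PHASE_M", "PHASE_G0",
           "CLASS_STEM", "CLASS_TA", "CryptState"]

# Cell-cycle phase codes.  Phase A is the stochastic Smith-Martin phase and
# consists entirely of G1; S, G2 and M form the deterministic phase B.
# G0 marks mature (non-cycling, non-growing) cells.
PHASE_A = 0
PHASE_S = 1
PHASE_G2 = 2
PHASE_M = 3
PHASE_G0 = 4

CLASS_STEM = 0
CLASS_TA = 1  # any non-stem proliferative cell (TA in the pedigree model)


@dataclass
class CryptState:
    """Positions, sizes, cycle state and labels of every cell in a crypt.

    All fields are equal-length 1-D numpy arrays; the i-th entry across all
    fields describes one cell.  ``generation`` is the TA generation index in
    the pedigree model (0 for stem cells, unused in the niche model).
    ``anchor_x`` records the basal attachment site of stem cells (NaN for
    unanchored cells).  ``clone`` is -1 for unmarked cells.
    """

    x: np.ndarray
    y: np.ndarray
    r: np.ndarray
    phase: np.ndarray
    clock: np.ndarray         # time elapsed in the current phase, hours
    cell_class: np.ndarray
    generation: np.ndarray
    li_label: np.ndarray
    clone: np.ndarray
    anchor_x: np.ndarray

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def mature(self) -> np.ndarray:
        return self.phase == PHASE_G0

    @property
    def proliferative(self) -> np.ndarray:
        return self.phase != PHASE_G0

    @classmethod
    def empty(cls, n: int) -> "CryptState":
        return cls(
            x=np.zeros(n), y=np.zeros(n), r=np.zeros(n),
            phase=np.zeros(n, dtype=np.int8),
            clock=np.zeros(n),
            cell_class=np.full(n, CLASS_TA, dtype=np.int8),
            generation=np.zeros(n, dtype=np.int16),
            li_label=np.zeros(n, dtype=bool),
            clone=np.full(n, -1, dtype=np.int32),
            anchor_x=np.full(n, np.nan),
        )

    def copy(self) -> "CryptState":
        return CryptState(**{f.name: getattr(self, f.name).copy()
                             for f in fields(self)})

    def take(self, idx) -> "CryptState":
        """New state containing only the selected cells."""
        return CryptState(**{f.name: getattr(self, f.name)[idx]
                             for f in fields(self)})

    def append(self, other: "CryptState") -> "CryptState":
        return CryptState(**{f.name: np.concatenate(
            [getattr(self, f.name), getattr(other, f.name)])
            for f in fields(self)})
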