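"""Crypt geometry: a laterally periodic 2D rectangle (unrolled cylinder).

The colonic crypt is a tubular pit; since the epithelium is a monolayer the
cylinder can be cut open and unrolled into a flat sheet with periodic borders
to the left and right.  ``y = 0`` is the (impenetrable) crypt base and
``y = height`` the orifice where cells leave the tissue.  Cells occupy
continuous positions (lattice-free).

The sheet dimensions are tuned to the murine descending colon: 22 cells
around the circumference and 32 cells along the length, so a perfectly
packed crypt holds exactly 704 cells.  "Perfectly packed" means a square
lattice of average-size cells at the mechanical equilibrium overlap, so the
effective cell diameter is ``2 * packing_radius - delta_eq``, where the
packing radius is the population-average cell radius (cycling cells are on
average larger than newborns; see
:func:`cryptabm.cell_cycle.reference_packing_radius`).  It defaults to the
mean birth radius when not given.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["CryptGeometry", "wrap_lateral", "lateral_delta", "pair_distance",
           "find_contacts", "row_index"]


@dataclass(frozen=True)
class CryptGeometry:
    """Dimensions of the unrolled crypt cylinder.

    Parameters
    ----------
    n_circumference
        Number of cells around the crypt circumference (default 22).
    n_length
        Number of cell rows along the crypt axis (default 32).
    mean_radius
        Mean cell radius in micrometres (default 5).
    delta_eq
        Equilibrium overlap between neighbouring cells in micrometres;
        enters the effective cell diameter so that exactly
        ``n_circumference * n_length`` relaxed cells tile the sheet.
    packing_radius
        Population-average cell radius used for the sheet fine-tuning;
        defaults to ``mean_radius``.
    """

    n_circumference: int = 22
    n_length: int = 32
    mean_radius: float = 5.0
    delta_eq: float = 0.5
    packing_radius: float | None = None
    width: float = field(init=False)
    height: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_circumference < 1 or self.n_length < 1:
            raise ValueError("cell counts must be positive")
        if self.mean_radius <= 0:
            raise ValueError("mean_radius must be positive")
        if self.packing_radius is None:
            object.__setattr__(self, "packing_radius", self.mean_radius)
        if not 0 <= self.delta_eq < 2 * self.packing_radius:
            raise ValueError("delta_eq must be in [0, cell diameter)")
        d_eff = self.effective_diameter
        object.__setattr__(self, "width", self.n_circumference * d_eff)
        object.__setattr__(self, "height", self.n_length * d_eff)

    @property
    def effective_diameter(self) -> float:
        """Centre-to-centre spacing of relaxed average cells."""
        return 2.0 * self.packing_radius - self.delta_eq

    @property
    def capacity(self) -> int:
        """Number of cells the sheet holds at perfect packing."""
        return self.n_circumference * self.n_length

    def row_height(self) -> float:
        return self.height / self.n_length


def wrap_lateral(x, geometry: CryptGeometry):
    """Wrap lateral coordinate(s) into ``[0, width)``.

    ``np.mod(-eps, w)`` can round to exactly ``w``; such values are
    folded back to 0 to keep the half-open contract.
    """
    w = geometry.width
    out = np.mod(x, w)
    return np.where(out >= w, 0.0, out)[()]


def lateral_delta(x1, x2, geometry: CryptGeometry):
    """Signed minimal-image lateral displacement from ``x2`` to ``x1``."""
    w = geometry.width
    d = np.mod(np.asarray(x1) - np.asarray(x2) + 0.5 * w, w) - 0.5 * w
    return d


def pair_distance(x1, y1, x2, y2, geometry: CryptGeometry):
    """Euclidean distance with the periodic lateral metric."""
    dx = lateral_delta(x1, x2, geometry)
    dy = np.asarray(y1) - np.asarray(y2)
    return np.hypot(dx, dy)


# y is unbounded above only transiently (cells above the orifice are removed
# at the end of the step); a box far taller than any crypt keeps the KD-tree
# periodic in x only.
_Y_BOX = 1e9


def find_contacts(x, y, r, geometry: CryptGeometry, reach: float = 0.0):
    """All unordered cell pairs within contact or attraction range.

    A pair ``(i, j)`` is returned iff the periodic centre distance is
    strictly less than ``r[i] + r[j] + reach``.  ``reach = 0`` selects
    physically overlapping cells only; a positive reach models filopodia
    that let separated cells attract each other.

    Returns
    -------
    (i, j) : pair of int arrays with ``i < j``.
    """
    if reach < 0:
        raise ValueError("reach must be non-negative")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = np.asarray(r, dtype=float)
    n = x.size
    if n < 2:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    pts = np.column_stack([np.mod(x, geometry.width), y])
    tree = cKDTree(pts, boxsize=[geometry.width, _Y_BOX])
    cutoff = 2.0 * float(r.max()) + reach
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if pairs.size == 0:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    i, j = pairs[:, 0], pairs[:, 1]
    d = pair_distance(x[i], y[i], x[j], y[j], geometry)
    keep = d < r[i] + r[j] + reach
    return i[keep], j[keep]


def row_index(y, geometry: CryptGeometry):
    """0-based crypt row of a cell centre: ``floor(y / row_height)``.

    Rows are half-open bins of equal height; values at or above the orifice
    clamp to the top row.
    """
    idx = np.floor(np.asarray(y) / geometry.row_height()).astype(int)
    return np.clip(idx, 0, geometry.n_length - 1)
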