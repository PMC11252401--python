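"""The unfolded hippocampal flatmap coordinate system.

The hippocampus, once unfolded, is parameterised by two intrinsic axes: the
long anterior-posterior (AP) axis running from tail to head, and the short
distal-proximal (PD) axis running from the subicular end towards the dentate
gyrus.  All hippocampal maps in this package live on a regular rectangular
lattice over these two axes, shared across species, with vertices stored in
row-major order (AP rows, PD columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class FlatmapGrid:
    """Regular 2D lattice over the intrinsic hippocampal coordinates.

    Attributes
    ----------
    n_ap : int
        Number of rows along the anterior-posterior axis.
    n_pd : int
        Number of columns along the distal-proximal axis.
    ap_coord : ndarray, shape (n_ap * n_pd,)
        Per-vertex AP coordinate in [0, 1]; 0 = posterior (tail),
        1 = anterior (head).  Bin-centre values, row-major vertex order.
    pd_coord : ndarray, shape (n_ap * n_pd,)
        Per-vertex PD coordinate in [0, 1]; 0 = distal (subicular end),
        1 = proximal (dentate gyrus end).
    """

    n_ap: int
    n_pd: int
    ap_coord: np.ndarray = field(repr=False)
    pd_coord: np.ndarray = field(repr=False)

    @property
    def n_vertices(self) -> int:
        return self.n_ap * self.n_pd

    def vertex_index(self, i: int, j: int) -> int:
        """Row-major vertex index of AP row ``i``, PD column ``j``."""
        if not (0 <= i < self.n_ap and 0 <= j < self.n_pd):
            raise IndexError(f"(i={i}, j={j}) outside {self.n_ap}x{self.n_pd} grid")
        return i * self.n_pd + j

    def __eq__(self, other) -> bool:
        if not isinstance(other, FlatmapGrid):
            return NotImplemented
        return (
            self.n_ap == other.n_ap
            and self.n_pd == other.n_pd
            and np.array_equal(self.ap_coord, other.ap_coord)
            and np.array_equal(self.pd_coord, other.pd_coord)
        )

    def __hash__(self):
        return hash((self.n_ap, self.n_pd))


def make_flatmap_grid(n_ap: int, n_pd: int) -> FlatmapGrid:
    """Build the bin-centre lattice of a regular ``n_ap`` x ``n_pd`` flatmap.

    Vertex ``(i, j)`` (row-major index ``i * n_pd + j``) has coordinates
    ``ap = (i + 0.5) / n_ap`` and ``pd = (j + 0.5) / n_pd``.

    Raises
    ------
    ValueError
        If either dimension is not an integer >= 2.
    """
    for name, v in (("n_ap", n_ap), ("n_pd", n_pd)):
        if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
            raise ValueError(f"{name} must be an integer, got {v!r}")
        if v < 2:
            raise ValueError(f"{name} must be >= 2, got {v}")
    i, j = np.meshgrid(np.arange(n_ap), np.arange(n_pd), indexing="ij")
    ap = (i.ravel() + 0.5) / n_ap
    pd = (j.ravel() + 0.5) / n_pd
    return FlatmapGrid(n_ap=int(n_ap), n_pd=int(n_pd), ap_coord=ap, pd_coord=pd)
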