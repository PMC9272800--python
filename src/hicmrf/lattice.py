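"""Two-dimensional lattice over contact-matrix bin pairs.

Each retained entry (i, j) of the contact matrix is a lattice *site*; the
neighbours of site s = (i, j) are the four adjacent matrix entries
(i±1, j) and (i, j±1), restricted to the retained region.  Simulated
datasets use a full rectangular lattice; real upper-triangle regions use a
masked one.  Sites are numbered row-major over the retained cells, which
matches the dense upper-triangle enumeration order used by the IO layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PairLattice"]


@dataclass(frozen=True)
class PairLattice:
    """Neighbourhood structure over bin pairs.

    Parameters
    ----------
    rows, cols:
        Shape of the enclosing rectangular grid.
    mask:
        Boolean (rows, cols) array marking retained cells.  ``None`` keeps
        the full rectangle.

    Notes
    -----
    Precomputes, for vectorized sweeps:

    - ``site_of_cell``: (rows, cols) int array, -1 for off-lattice cells;
    - ``nbr_idx``: (n_sites, 4) neighbour site indices, ``n_sites`` used as
      a sentinel for missing neighbours;
    - ``edges``: (n_edges, 2) unordered neighbour pairs, each counted once;
    - ``colors``: (n_sites,) checkerboard colour (i+j) mod 2, so that all
      sites of one colour are conditionally independent given the other.
    """

    rows: int
    cols: int
    mask: np.ndarray | None = None

    site_of_cell: np.ndarray = field(init=False, repr=False, compare=False)
    sites_rc: np.ndarray = field(init=False, repr=False, compare=False)
    nbr_idx: np.ndarray = field(init=False, repr=False, compare=False)
    edges: np.ndarray = field(init=False, repr=False, compare=False)
    colors: np.ndarray = field(init=False, repr=False, compare=False)
    color_order: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("lattice shape must be positive")
        mask = self.mask
        if mask is None:
            mask = np.ones((self.rows, self.cols), dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (self.rows, self.cols):
                raise ValueError("mask shape does not match lattice shape")
            if not mask.any():
                raise ValueError("lattice mask retains no sites")
        object.__setattr__(self, "mask", mask)

        site_of_cell = np.full((self.rows, self.cols), -1, dtype=np.int64)
        rr, cc = np.nonzero(mask)  # row-major order
        n = rr.size
        site_of_cell[rr, cc] = np.arange(n)
        object.__setattr__(self, "site_of_cell", site_of_cell)
        object.__setattr__(self, "sites_rc", np.column_stack([rr, cc]))

        # neighbour site index per direction; n acts as "missing" sentinel
        padded = np.full((self.rows + 2, self.cols + 2), -1, dtype=np.int64)
        padded[1:-1, 1:-1] = site_of_cell
        up = padded[0:-2, 1:-1][rr, cc]
        down = padded[2:, 1:-1][rr, cc]
        left = padded[1:-1, 0:-2][rr, cc]
        right = padded[1:-1, 2:][rr, cc]
        nbr = np.column_stack([up, down, left, right])
        nbr[nbr < 0] = n
        object.__setattr__(self, "nbr_idx", nbr)

        # unordered edges: count each pair once via down and right links
        e0 = []
        e1 = []
        for d in (down, right):
            ok = d >= 0
            e0.append(np.arange(n)[ok])
            e1.append(d[ok])
        edges = np.column_stack([np.concatenate(e0), np.concatenate(e1)])
        object.__setattr__(self, "edges", edges)
        colors = ((rr + cc) % 2).astype(np.int8)
        object.__setattr__(self, "colors", colors)
        # scan order for chromatic sweeps: all even-colour sites, then odd
        order = np.concatenate([np.nonzero(colors == 0)[0], np.nonzero(colors == 1)[0]])
        object.__setattr__(self, "color_order", order.astype(np.int64))

    # -- constructors -------------------------------------------------

    @classmethod
    def rectangle(cls, rows: int, cols: int) -> "PairLattice":
        return cls(rows, cols)

    @classmethod
    def upper_triangle(cls, n_bins: int) -> "PairLattice":
        """Lattice over the dense upper triangle (diagonal included) of an
        ``n_bins`` x ``n_bins`` contact matrix."""
        mask = np.triu(np.ones((n_bins, n_bins), dtype=bool))
        return cls(n_bins, n_bins, mask)

    # -- queries ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def n_sites(self) -> int:
        return self.sites_rc.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def neighbors(self, s: int) -> list[int]:
        """Neighbour site indices of site ``s`` (2--4 of them)."""
        row = self.nbr_idx[s]
        return [int(t) for t in row if t < self.n_sites]

    def degree(self) -> np.ndarray:
        return (self.nbr_idx < self.n_sites).sum(axis=1)

    def neighbor_label_counts(self, z: np.ndarray, K: int) -> np.ndarray:
        """(n_sites, K) counts of each label among the neighbours of each site."""
        z_ext = np.append(np.asarray(z, dtype=np.int64), -1)  # sentinel slot
        nbr_labels = z_ext[self.nbr_idx]
        counts = np.empty((self.n_sites, K), dtype=np.int64)
        for k in range(K):
            counts[:, k] = (nbr_labels == k + 1).sum(axis=1)
        return counts

    def concordant_pairs(self, z: np.ndarray) -> int:
        """Number of unordered neighbour pairs with equal labels."""
        z = np.asarray(z)
        return int((z[self.edges[:, 0]] == z[self.edges[:, 1]]).sum())

    def to_grid(self, values: np.ndarray, fill=0) -> np.ndarray:
        """Scatter per-site values back onto the (rows, cols) grid."""
        values = np.asarray(values)
        out = np.full((self.rows, self.cols), fill, dtype=values.dtype)
        out[self.sites_rc[:, 0], self.sites_rc[:, 1]] = values
        return out
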