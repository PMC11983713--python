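"""Geometry, topology and periodic-boundary primitives for 3-site water.

A :class:`Configuration` is the single source of geometric truth: element
labels, Cartesian positions (Å), optional velocities (Å/fs) and an optional
orthorhombic cell.  Molecules are stored in canonical (O, H1, H2) atom order;
topology is either supplied or inferred from O–H distances (< 1.3 Å).

Only orthorhombic cells are supported; minimum-image displacements therefore
reduce to a per-axis nearest-integer wrap.  For displacements of exactly half
a box length the negative-sign image is chosen deterministically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .units import MASS

__all__ = [
    "Configuration",
    "NeighborList",
    "ConfigurationError",
    "minimum_image_displacement",
    "build_neighbor_list",
    "wrap_molecules",
    "infer_topology",
]

#: O–H bond-detection threshold used when inferring molecules from geometry, Å
OH_BOND_CUTOFF = 1.3


class ConfigurationError(ValueError):
    """Raised for invalid water configurations (bad topology, bad cell)."""


def infer_topology(species: np.ndarray, positions: np.ndarray,
                   cell: np.ndarray | None = None) -> np.ndarray:
    """Assign each atom to a molecule by O–H distance < 1.3 Å.

    Returns a permutation of atom indices grouping each molecule as
    (O, H1, H2) with H1/H2 in input order.
    """
    species = np.asarray(species)
    o_idx = np.flatnonzero(species == "O")
    h_idx = np.flatnonzero(species == "H")
    bad = np.flatnonzero(~np.isin(species, ("O", "H")))
    if bad.size:
        raise ConfigurationError(
            f"unsupported element(s) {sorted(set(species[bad]))}: "
            "only O and H (water) are handled")
    if h_idx.size != 2 * o_idx.size:
        raise ConfigurationError(
            f"{o_idx.size} O and {h_idx.size} H atoms cannot form water")
    order = []
    taken = np.zeros(len(species), dtype=bool)
    for o in o_idx:
        d = positions[h_idx] - positions[o]
        if cell is not None:
            d -= np.round(d / cell) * cell
        r = np.linalg.norm(d, axis=1)
        near = h_idx[(r < OH_BOND_CUTOFF) & ~taken[h_idx]]
        if near.size != 2:
            raise ConfigurationError(
                f"O atom {o} has {near.size} bonded H (expected 2); "
                "cannot infer water topology")
        taken[near] = True
        order.extend([o, *near])
    return np.asarray(order, dtype=np.intp)


@dataclass
class Configuration:
    """Atomic species, positions and (optional) velocities / orthorhombic cell.

    Atoms are held in canonical molecule order: atom ``3*m`` is the oxygen of
    molecule ``m``, followed by its two hydrogens.
    """

    species: np.ndarray          # (N,) of 'O'/'H'
    positions: np.ndarray        # (N, 3) Å
    velocities: np.ndarray | None = None  # (N, 3) Å/fs
    cell: np.ndarray | None = None        # (3,) box lengths, Å
    charges: np.ndarray | None = None     # (N,) e, optional annotation

    def __post_init__(self) -> None:
        self.species = np.asarray(self.species, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.species), 3):
            raise ConfigurationError("positions must be (N, 3)")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float).reshape(3)
            if np.any(self.cell <= 0):
                raise ConfigurationError("box lengths must be positive")
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)
        self._validate_topology()

    def _validate_topology(self) -> None:
        n = len(self.species)
        if n % 3:
            raise ConfigurationError(f"atom count {n} is not 3 × molecules")
        sp = self.species.reshape(-1, 3)
        if not (np.all(sp[:, 0] == "O") and np.all(sp[:, 1:] == "H")):
            # attempt canonicalization
            order = infer_topology(self.species, self.positions, self.cell)
            self.species = self.species[order]
            self.positions = self.positions[order]
            if self.velocities is not None:
                self.velocities = self.velocities[order]
            if self.charges is not None:
                self.charges = self.charges[order]

    # -- convenience views -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.species)

    @property
    def n_molecules(self) -> int:
        return self.n_atoms // 3

    @property
    def molecule_index(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_molecules), 3)

    @property
    def is_oxygen(self) -> np.ndarray:
        return np.asarray(self.species == "O")

    @property
    def masses(self) -> np.ndarray:
        return np.asarray([MASS[s] for s in self.species])

    @property
    def periodic(self) -> bool:
        return self.cell is not None

    def copy(self) -> "Configuration":
        return Configuration(
            self.species.copy(), self.positions.copy(),
            None if self.velocities is None else self.velocities.copy(),
            None if self.cell is None else self.cell.copy(),
            None if self.charges is None else self.charges.copy(),
        )

    def with_positions(self, positions: np.ndarray) -> "Configuration":
        new = self.copy()
        new.positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        return new

    def validate_cell(self, max_cutoff: float) -> None:
        """Enforce minimum-image validity: every box length > 2 × cutoff."""
        if self.cell is not None and np.any(self.cell <= 2.0 * max_cutoff):
            raise ConfigurationError(
                f"box {self.cell} too small for cutoff {max_cutoff} Å "
                "(minimum image requires L > 2 × cutoff)")


def displacement_matrix(config: Configuration) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs minimum-image displacements d[i, j] = r_j − r_i and distances.

    The diagonal distance is set to +inf so cutoff masks never self-select.
    """
    pos = config.positions
    d = pos[None, :, :] - pos[:, None, :]
    if config.cell is not None:
        # nearest-integer wrap; ties at exactly L/2 resolve to the negative image
        d -= np.round(d / config.cell) * config.cell
        half = config.cell / 2
        on_boundary = d == half
        d = np.where(on_boundary, -half, d)
    r = np.linalg.norm(d, axis=-1)
    np.fill_diagonal(r, np.inf)
    return d, r


def minimum_image_displacement(config: Configuration, i: int, j: int) -> np.ndarray:
    """Shortest periodic image of r_j − r_i (plain difference for clusters)."""
    d = config.positions[j] - config.positions[i]
    if config.cell is not None:
        d = d - np.round(d / config.cell) * config.cell
        half = config.cell / 2
        d = np.where(d == half, -half, d)
    return d


@dataclass
class NeighborList:
    """Symmetric pair list within a cutoff (minimum-image distances)."""

    cutoff: float
    pairs: np.ndarray            # (P, 2) i < j
    displacements: np.ndarray    # (P, 3) r_j − r_i, min image
    distances: np.ndarray        # (P,)
    n_atoms: int = 0

    def neighbors_of(self, i: int) -> np.ndarray:
        mask = (self.pairs[:, 0] == i) | (self.pairs[:, 1] == i)
        p = self.pairs[mask]
        return np.where(p[:, 0] == i, p[:, 1], p[:, 0])


def build_neighbor_list(config: Configuration, cutoff: float) -> NeighborList:
    """All pairs with minimum-image distance ≤ cutoff (O(N²) scan)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if config.periodic:
        config.validate_cell(cutoff)
    d, r = displacement_matrix(config)
    ii, jj = np.where(np.triu(r <= cutoff, k=1))
    return NeighborList(cutoff, np.column_stack([ii, jj]),
                        d[ii, jj], r[ii, jj], config.n_atoms)


def wrap_molecules(config: Configuration) -> Configuration:
    """Translate each molecule rigidly so its O atom lies in [0, L).

    Intramolecular geometry is untouched.  A no-op (with a warning) for
    clusters.
    """
    if config.cell is None:
        warnings.warn("wrap_molecules is a no-op for non-periodic clusters")
        return config.copy()
    new = config.copy()
    pos = new.positions.reshape(config.n_molecules, 3, 3)
    o = pos[:, 0, :]
    shift = -np.floor(o / config.cell) * config.cell
    pos += shift[:, None, :]
    new.positions = pos.reshape(-1, 3)
    return new

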