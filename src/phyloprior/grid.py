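"""Spatial frame shared by every layer: the equal-area landscape grid.

All per-cell layers (climate, presence, protection, human pressure, priority
ranks) are joined on ``cell_id``, an integer index that is contiguous from 0.
Coordinates are cell centres in kilometres on an equal-area plane, so planar
Euclidean distance is the distance used for buffers and dispersal limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LandscapeGrid", "ClimateStack", "PresenceMatrix"]


@dataclass(frozen=True)
class LandscapeGrid:
    """Equal-area grid of landscape cells.

    Parameters
    ----------
    cell_id : array of int
        Unique cell identifiers, contiguous from 0.
    x, y : array of float
        Cell-centre coordinates in km.
    area : array of float
        Cell area in km² (default construction uses a constant 400 km²,
        i.e. 20 x 20 km cells).
    """

    cell_id: np.ndarray
    x: np.ndarray
    y: np.ndarray
    area: np.ndarray
    shape: tuple[int, int] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        cid = np.asarray(self.cell_id)
        if cid.size == 0:
            raise ValueError("grid must contain at least one cell")
        if not np.array_equal(cid, np.arange(cid.size)):
            raise ValueError("cell ids must be unique and contiguous from 0")
        if np.any(np.asarray(self.area) <= 0):
            raise ValueError("cell areas must be strictly positive")
        if not (len(self.x) == len(self.y) == len(self.area) == cid.size):
            raise ValueError("grid column lengths differ")

    @property
    def n_cells(self) -> int:
        return int(self.cell_id.size)

    @property
    def coords(self) -> np.ndarray:
        """(n_cells, 2) array of cell-centre coordinates in km."""
        return np.column_stack([self.x, self.y])

    @classmethod
    def regular(cls, nx: int, ny: int, cell_size_km: float = 20.0) -> "LandscapeGrid":
        """Build a regular nx x ny lattice of square cells.

        Cells are numbered row-major from the north-west corner (row 0 is the
        northernmost), matching how the layers are exported.
        """
        if nx < 1 or ny < 1:
            raise ValueError("grid dimensions must be positive")
        jj, ii = np.meshgrid(np.arange(nx), np.arange(ny))
        x = (jj.ravel() + 0.5) * cell_size_km
        y = ((ny - 1 - ii.ravel()) + 0.5) * cell_size_km
        n = nx * ny
        return cls(
            cell_id=np.arange(n),
            x=x.astype(float),
            y=y.astype(float),
            area=np.full(n, cell_size_km**2, dtype=float),
            shape=(ny, nx),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.cell_id, "x": self.x, "y": self.y, "area": self.area}
        )


@dataclass(frozen=True)
class ClimateStack:
    """Per-cell environmental variables under one scenario.

    ``values`` is (n_cells, n_vars); ``scenario`` is ``"current"`` or
    ``"future-<name>"``. No missing values are permitted.
    """

    values: np.ndarray
    var_names: tuple[str, ...]
    scenario: str = "current"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != len(self.var_names):
            raise ValueError("values must be (n_cells, n_vars)")
        if np.any(~np.isfinite(v)):
            raise ValueError("climate stack contains missing/non-finite values")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "var_names", tuple(self.var_names))

    @property
    def n_cells(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_vars(self) -> int:
        return int(self.values.shape[1])

    def var(self, name: str) -> np.ndarray:
        return self.values[:, self.var_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.var_names))
        df.insert(0, "cell_id", np.arange(self.n_cells))
        return df


class PresenceMatrix:
    """Binary species x cell occupancy.

    Backed by a boolean (n_species, n_cells) array with an ordered species
    list; rows are species, columns are grid cell ids 0..n_cells-1.
    """

    def __init__(self, occupancy: np.ndarray, species: list[str]) -> None:
        occ = np.asarray(occupancy, dtype=bool)
        if occ.ndim != 2 or occ.shape[0] != len(species):
            raise ValueError("occupancy must be (n_species, n_cells)")
        if len(set(species)) != len(species):
            raise ValueError("duplicate species labels")
        self.occupancy = occ
        self.species = list(species)
        self._index = {s: i for i, s in enumerate(self.species)}

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_cells(self) -> int:
        return int(self.occupancy.shape[1])

    def cells_of(self, species: str) -> np.ndarray:
        """Occupied cell ids of one species, ascending."""
        return np.flatnonzero(self.occupancy[self._index[species]])

    def range_sizes(self) -> np.ndarray:
        return self.occupancy.sum(axis=1)

    def richness(self) -> np.ndarray:
        """Species count per cell."""
        return self.occupancy.sum(axis=0)

    def subset(self, species: list[str]) -> "PresenceMatrix":
        idx = [self._index[s] for s in species]
        return PresenceMatrix(self.occupancy[idx], list(species))

    def to_long(self) -> pd.DataFrame:
        sp_idx, cell = np.nonzero(self.occupancy)
        return pd.DataFrame(
            {"species": [self.species[i] for i in sp_idx], "cell_id": cell}
        )

    @classmethod
    def from_long(cls, df: pd.DataFrame, n_cells: int,
                  species: list[str] | None = None) -> "PresenceMatrix":
        if species is None:
            species = sorted(df["species"].unique())
        occ = np.zeros((len(species), n_cells), dtype=bool)
        index = {s: i for i, s in enumerate(species)}
        cells = df["cell_id"].to_numpy()
        if cells.size and (cells.min() < 0 or cells.max() >= n_cells):
            bad = cells[(cells < 0) | (cells >= n_cells)]
            raise ValueError(f"cell ids outside grid: {sorted(set(bad))[:5]}")
        for s, c in zip(df["species"], cells):
            occ[index[s], c] = True
        return cls(occ, species)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, PresenceMatrix)
            and self.species == other.species
            and np.array_equal(self.occupancy, other.occupancy)
        )

    def __repr__(self) -> str:
        return f"PresenceMatrix({self.n_species} species x {self.n_cells} cells)"
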