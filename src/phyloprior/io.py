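"""File formats: plain-text CSV layers joined on cell_id, plus Newick trees.

CSV is the canonical on-disk form for every per-cell layer; the grid table
is the spatial frame every other file is validated against. All round-trips
are exact (identity for integer layers, 1e-9 for branch lengths).
"""

from __future__ import annotations

import json
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .grid import ClimateStack, LandscapeGrid, PresenceMatrix
from .phylo import BranchFeature
from .prioritize import PerformanceCurves, RankMap

__all__ = [
    "write_grid", "read_grid",
    "write_climate", "read_climate",
    "write_presences", "read_presences",
    "write_tree", "read_tree",
    "write_layer", "read_layer",
    "write_features", "read_features",
    "write_rank", "read_rank",
    "write_curves",
    "write_json",
]


def _check_cells(cells: np.ndarray, grid: LandscapeGrid) -> None:
    bad = np.setdiff1d(np.asarray(cells), grid.cell_id)
    if bad.size:
        raise ValueError(f"cell ids absent from the grid: {bad[:5].tolist()}")


def write_grid(grid: LandscapeGrid, path: str | Path) -> None:
    grid.to_frame().to_csv(path, index=False)


def read_grid(path: str | Path) -> LandscapeGrid:
    df = pd.read_csv(path)
    nx = df["x"].nunique()
    ny = df["y"].nunique()
    shape = (ny, nx) if nx * ny == len(df) else None
    return LandscapeGrid(
        cell_id=df["cell_id"].to_numpy(),
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        area=df["area"].to_numpy(float),
        shape=shape,
    )


def write_climate(climate: ClimateStack, path: str | Path) -> None:
    df = climate.to_frame()
    df.insert(1, "scenario", climate.scenario)
    df.to_csv(path, index=False)


def read_climate(path: str | Path, grid: LandscapeGrid | None = None) -> ClimateStack:
    df = pd.read_csv(path)
    scenario = str(df.pop("scenario").iloc[0]) if "scenario" in df else "current"
    cells = df.pop("cell_id").to_numpy()
    if grid is not None:
        _check_cells(cells, grid)
    return ClimateStack(df.to_numpy(float), tuple(df.columns), scenario)


def write_presences(presences: PresenceMatrix, path: str | Path) -> None:
    presences.to_long().to_csv(path, index=False)


def read_presences(path: str | Path, grid: LandscapeGrid) -> PresenceMatrix:
    df = pd.read_csv(path)
    _check_cells(df["cell_id"].to_numpy(), grid)
    return PresenceMatrix.from_long(df, grid.n_cells)


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_layer(values: np.ndarray, path: str | Path, name: str = "value") -> None:
    pd.DataFrame({"cell_id": np.arange(len(values)), name: values}).to_csv(
        path, index=False)


def read_layer(path: str | Path, grid: LandscapeGrid | None = None) -> np.ndarray:
    df = pd.read_csv(path)
    if grid is not None:
        _check_cells(df["cell_id"].to_numpy(), grid)
        if len(df) != grid.n_cells:
            raise ValueError("layer does not cover the full grid")
    return df.set_index("cell_id").sort_index().iloc[:, 0].to_numpy()


def write_features(features: list[BranchFeature], path: str | Path) -> None:
    rows = [
        {"feature_id": f.branch_id, "weight": f.weight, "cell_id": c}
        for f in features for c in sorted(f.cells)
    ]
    pd.DataFrame(rows, columns=["feature_id", "weight", "cell_id"]).to_csv(
        path, index=False)


def read_features(path: str | Path, grid: LandscapeGrid | None = None
                  ) -> list[BranchFeature]:
    df = pd.read_csv(path)
    if grid is not None:
        _check_cells(df["cell_id"].to_numpy(), grid)
    out = []
    for fid, g in df.groupby("feature_id", sort=False):
        out.append(BranchFeature(
            branch_id=str(fid),
            weight=float(g["weight"].iloc[0]),
            cells=frozenset(int(c) for c in g["cell_id"]),
        ))
    return out


def write_rank(rank: RankMap, path: str | Path) -> None:
    pd.DataFrame({
        "cell_id": np.arange(rank.n_cells),
        "removal_order": rank.removal_order,
        "priority": rank.priority,
    }).to_csv(path, index=False)


def read_rank(path: str | Path) -> RankMap:
    df = pd.read_csv(path).sort_values("cell_id")
    return RankMap(df["removal_order"].to_numpy(int))


def write_curves(curves: PerformanceCurves, path: str | Path,
                 every: int = 1) -> None:
    ks = range(0, curves.fractions.size, every)
    rows = [
        {"feature_id": fid, "f": curves.fractions[k],
         "retention": curves.retention[j, k]}
        for j, fid in enumerate(curves.feature_ids) for k in ks
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
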