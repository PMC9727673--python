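"""Iterative marginal-loss cell-removal prioritization (Zonation-style).

Given weighted binary feature layers over a grid, the landscape is eroded
one cell at a time: at every step the cell whose removal sacrifices the
least conservation value is discarded, so cells removed late are the most
irreplaceable. Two marginal-loss rules are supported, with
``q[j, i] = a[j, i] / (remaining occurrences of feature j)``:

* CAZ (core-area zonation):      loss(i) = max_j w[j] * q[j, i] / c[i]
* ABF (additive benefit):        loss(i) = sum_j w[j] * q[j, i] / c[i]

CAZ guards the single most irreplaceable feature in a cell (protecting long
branches), ABF the weighted total. Cells locked in by a mask (existing
protected areas) are removed only after every free cell, which pins them to
the top of the priority ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid import PresenceMatrix

__all__ = [
    "FeatureSet",
    "RankMap",
    "PerformanceCurves",
    "marginal_loss",
    "run_prioritization",
    "top_fraction",
    "scenario_overlap",
    "compare_rank_maps",
    "build_species_featureset",
]

RULES = ("caz", "abf")


@dataclass
class FeatureSet:
    """Feature x cell occurrences with weights, per-cell cost and mask.

    ``mask[i] = 1`` locks cell i in (removed last); cost defaults to 1.
    """

    occurrence: np.ndarray          # (F, C) in {0, 1}
    weights: np.ndarray             # (F,) > 0
    cost: np.ndarray | None = None  # (C,) > 0
    mask: np.ndarray | None = None  # (C,) in {0, 1}
    feature_ids: list[str] | None = None

    def __post_init__(self) -> None:
        occ = np.asarray(self.occurrence, dtype=bool)
        if occ.ndim != 2:
            raise ValueError("occurrence must be (features, cells)")
        F, C = occ.shape
        if np.any(occ.sum(axis=1) == 0):
            raise ValueError("every feature must occupy at least one cell")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (F,) or np.any(w <= 0):
            raise ValueError("weights must be positive, one per feature")
        cost = np.ones(C) if self.cost is None else np.asarray(self.cost, float)
        if cost.shape != (C,) or np.any(cost <= 0):
            raise ValueError("cost must be positive, one per cell")
        mask = np.zeros(C, int) if self.mask is None else np.asarray(self.mask, int)
        if mask.shape != (C,) or not np.isin(mask, [0, 1]).all():
            raise ValueError("mask must be 0 (free) or 1 (locked-in) per cell")
        ids = self.feature_ids or [f"f{j}" for j in range(F)]
        if len(ids) != F:
            raise ValueError("feature_ids length mismatch")
        self.occurrence, self.weights, self.cost, self.mask = occ, w, cost, mask
        self.feature_ids = list(ids)

    @property
    def n_features(self) -> int:
        return self.occurrence.shape[0]

    @property
    def n_cells(self) -> int:
        return self.occurrence.shape[1]


@dataclass(frozen=True)
class RankMap:
    """Removal order (1 = removed first) and derived priority per cell.

    ``priority[i] = removal_order[i] / n_cells`` is the fraction of the
    landscape already gone when cell i is discarded — higher means the cell
    survived longer and is more important. The top fraction f of the
    landscape is the set of cells with the highest priority.
    """

    removal_order: np.ndarray

    def __post_init__(self) -> None:
        order = np.asarray(self.removal_order, dtype=int)
        n = order.size
        if not np.array_equal(np.sort(order), np.arange(1, n + 1)):
            raise ValueError("removal_order must be a permutation of 1..n")
        object.__setattr__(self, "removal_order", order)

    @property
    def n_cells(self) -> int:
        return int(self.removal_order.size)

    @property
    def priority(self) -> np.ndarray:
        return self.removal_order / self.n_cells


@dataclass(frozen=True)
class PerformanceCurves:
    """Per-feature retention against the fraction of landscape removed.

    ``retention[j, k]`` is the fraction of feature j's occurrences still
    present after k cells (fraction ``fractions[k]``) have been removed;
    every curve starts at 1 and ends at 0.
    """

    fractions: np.ndarray       # (n+1,) removed fraction grid
    retention: np.ndarray      # (F, n+1)
    feature_ids: list[str]

    def retention_at(self, f: float) -> np.ndarray:
        """Retention of every feature once a fraction f of cells is removed."""
        k = int(np.searchsorted(self.fractions, f, side="right")) - 1
        return self.retention[:, k]


def _loss_matrix(occ: np.ndarray, weights: np.ndarray, totals: np.ndarray,
                 cost: np.ndarray, cells: np.ndarray, rule: str) -> np.ndarray:
    """Marginal loss for each cell in ``cells`` given remaining totals."""
    alive = totals > 0
    if not alive.any():
        return np.zeros(cells.size)
    wq = (weights[alive] / totals[alive])[:, None] * occ[np.ix_(alive, cells)]
    if rule == "caz":
        loss = wq.max(axis=0)
    elif rule == "abf":
        loss = wq.sum(axis=0)
    else:
        raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")
    return loss / cost[cells]


def marginal_loss(features: FeatureSet, remaining: np.ndarray, cell: int,
                  rule: str = "caz") -> float:
    """Marginal loss of removing ``cell`` from the remaining landscape.

    ``remaining`` is a boolean mask of cells still present (``cell`` must be
    among them); feature totals are recomputed from it.
    """
    remaining = np.asarray(remaining, dtype=bool)
    if not remaining[cell]:
        raise ValueError(f"cell {cell} has already been removed")
    totals = features.occurrence[:, remaining].sum(axis=1).astype(float)
    return float(_loss_matrix(features.occurrence, features.weights, totals,
                              features.cost, np.array([cell]), rule)[0])


def run_prioritization(
    features: FeatureSet, rule: str = "caz", seed: int = 0
) -> tuple[RankMap, PerformanceCurves]:
    """Erode the landscape cell by cell under the given marginal-loss rule.

    Strictly iterative: remaining feature totals are updated after every
    removal and losses recomputed from them. Exact loss ties are broken by
    a seeded random choice. Masked (locked-in) cells are only removed after
    all free cells, with the same rule applied within the masked stratum, so
    they occupy the top of the ranking.
    """
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")
    occ = features.occurrence
    F, C = occ.shape
    rng = np.random.default_rng(seed)
    totals = occ.sum(axis=1).astype(float)
    initial = totals.copy()
    removal_order = np.zeros(C, dtype=int)
    retention = np.empty((F, C + 1))
    retention[:, 0] = 1.0
    remaining = np.ones(C, dtype=bool)
    step = 0
    for stratum in (0, 1):
        in_stratum = features.mask == stratum
        while True:
            cells = np.flatnonzero(remaining & in_stratum)
            if cells.size == 0:
                break
            loss = _loss_matrix(occ, features.weights, totals, features.cost,
                                cells, rule)
            m = loss.min()
            tied = cells[loss == m]
            chosen = int(tied[0]) if tied.size == 1 else int(rng.choice(tied))
            remaining[chosen] = False
            totals -= occ[:, chosen]
            step += 1
            removal_order[chosen] = step
            retention[:, step] = totals / initial
    curves = PerformanceCurves(np.arange(C + 1) / C, retention,
                               list(features.feature_ids))
    return RankMap(removal_order), curves


def top_fraction(rank: RankMap, f: float) -> set[int]:
    """The ceil(f * n_cells) cells removed last (the top-priority set)."""
    if not 0 < f <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = int(np.ceil(f * rank.n_cells))
    return set(np.flatnonzero(rank.removal_order > rank.n_cells - k).tolist())


def scenario_overlap(current_top: set[int], future_top: set[int]
                     ) -> dict[str, set[int]]:
    """Partition priority areas across scenarios: kept, lost and gained."""
    return {
        "overlapped": set(current_top) & set(future_top),
        "disappeared": set(current_top) - set(future_top),
        "newly_formed": set(future_top) - set(current_top),
    }


def compare_rank_maps(rank_a: RankMap, rank_b: RankMap) -> float:
    """Pearson correlation of two priority maps across cells."""
    if rank_a.n_cells != rank_b.n_cells:
        raise ValueError("rank maps cover different grids")
    a, b = rank_a.priority, rank_b.priority
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance priority map")
    return float(stats.pearsonr(a, b).statistic)


def build_species_featureset(
    presences: PresenceMatrix,
    cost: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> FeatureSet:
    """Species-based features: one unit-weight feature per species (the
    traditional richness-driven prioritization this package contrasts with
    the branch-weighted one)."""
    occ = presences.occupancy
    keep = occ.sum(axis=1) > 0
    return FeatureSet(
        occurrence=occ[keep],
        weights=np.ones(int(keep.sum())),
        cost=cost,
        mask=mask,
        feature_ids=[s for s, k in zip(presences.species, keep) if k],
    )
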