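"""Protection accounting: gap analysis, coverage, pressure and novelty.

This module answers "how well does a protected-area (PA) network cover the
tree of life?": which cells count as protected, what fraction of each
species' or branch's range a representation target demands, how achieved
protection classifies into gap classes, how mean branch coverage responds
to PA expansion, how protection distributes over phylogenetic-diversity
classes and human-pressure classes, and which cells sit in novel climate
(outside the area of applicability of the models).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .grid import ClimateStack
from .phylo import BranchFeature
from .prioritize import RankMap

logger = logging.getLogger(__name__)

__all__ = [
    "GapRecord",
    "protected_cells",
    "conservation_target",
    "gap_classify",
    "gap_table",
    "mean_branch_coverage",
    "pd_class_protection",
    "hmi_classify",
    "group_hmi_summary",
    "aoa_novel_climate",
    "expansion_report",
]

GAP_CLASSES = ("unprotected", "gap", "partial_gap", "covered")
HMI_CLASSES = ("low", "moderate", "high")


@dataclass(frozen=True)
class GapRecord:
    """Representation-target accounting for one species or branch."""

    unit_id: str
    range_cells: int
    target: float            # fraction of range required protected
    achieved: float          # protected-in-range / (target * range)
    label: str               # one of GAP_CLASSES


def protected_cells(pa_fraction: np.ndarray, cutoff: float = 0.3) -> np.ndarray:
    """A cell is protected when PA polygons cover strictly more than
    ``cutoff`` of its area (default 30%)."""
    pa = np.asarray(pa_fraction, dtype=float)
    if np.any((pa < 0) | (pa > 1)):
        raise ValueError("PA fractions must lie in [0, 1]")
    return pa > cutoff


def conservation_target(
    range_area: float,
    lower: float = 1_000.0,
    upper: float = 250_000.0,
    floor: float = 0.1,
) -> float:
    """Representation target as a fraction of range area (km²).

    Ranges below ``lower`` need full protection (target 1); ranges above
    ``upper`` need only ``floor``; between the two the target interpolates
    log-linearly — the standard range-size-scaled target rule.
    """
    if range_area <= 0:
        raise ValueError("range area must be positive")
    if range_area <= lower:
        return 1.0
    if range_area >= upper:
        return floor
    frac = (np.log(range_area) - np.log(lower)) / (np.log(upper) - np.log(lower))
    return float(1.0 - (1.0 - floor) * frac)


def gap_classify(
    protected_in_range: int,
    range_cells: int,
    target: float,
    unit_id: str = "?",
) -> GapRecord:
    """Classify a unit by achieved protection relative to its target.

    unprotected: nothing of the range is protected; gap: at most 20% of the
    target achieved; partial_gap: 20-90%; covered: above 90%.
    """
    if not 0 < target <= 1:
        raise ValueError("target must be in (0, 1]")
    if range_cells <= 0:
        raise ValueError("unit must occupy at least one cell")
    achieved = protected_in_range / (target * range_cells)
    if protected_in_range == 0:
        label = "unprotected"
    elif achieved <= 0.2:
        label = "gap"
    elif achieved <= 0.9:
        label = "partial_gap"
    else:
        label = "covered"
    return GapRecord(unit_id, range_cells, target, achieved, label)


def gap_table(
    units: list[BranchFeature] | dict[str, set[int]],
    protected: set[int] | np.ndarray,
    cell_area: float = 400.0,
    lower: float = 1_000.0,
    upper: float = 250_000.0,
    floor: float = 0.1,
) -> list[GapRecord]:
    """Gap records for a collection of branches (or species cell sets).

    Range area is occupied cells x cell area; the same target rule applies
    to species and branches alike.
    """
    if isinstance(protected, np.ndarray):
        protected = set(np.flatnonzero(protected).tolist())
    if isinstance(units, dict):
        items = list(units.items())
    else:
        items = [(b.branch_id, set(b.cells)) for b in units]
    records = []
    for uid, cells in items:
        target = conservation_target(len(cells) * cell_area, lower, upper, floor)
        records.append(gap_classify(len(cells & protected), len(cells), target, uid))
    return records


def mean_branch_coverage(
    branches: list[BranchFeature], protected: set[int] | np.ndarray
) -> float:
    """Unweighted mean over branches of the protected fraction of their
    occupied cells."""
    if isinstance(protected, np.ndarray):
        protected = set(np.flatnonzero(protected).tolist())
    if not branches:
        raise ValueError("no branches")
    covs = [len(set(b.cells) & protected) / len(b.cells) for b in branches]
    return float(np.mean(covs))


def pd_class_protection(
    pd_classes: np.ndarray, protected: np.ndarray
) -> dict[int, float]:
    """Fraction of cells protected within each PD class."""
    pd_classes = np.asarray(pd_classes)
    protected = np.asarray(protected, dtype=bool)
    out = {}
    for c in np.unique(pd_classes):
        members = pd_classes == c
        if members.sum() == 0:
            raise ValueError(f"empty PD class {c}")
        out[int(c)] = float(protected[members].mean())
    return out


def hmi_classify(hmi: np.ndarray) -> np.ndarray:
    """Human-pressure classes: low (< 0.1), moderate ([0.1, 0.4)),
    high (>= 0.4)."""
    hmi = np.asarray(hmi, dtype=float)
    if np.any((hmi < 0) | (hmi > 1)):
        raise ValueError("HMI must lie in [0, 1]")
    classes = np.full(hmi.shape, "moderate", dtype=object)
    classes[hmi < 0.1] = "low"
    classes[hmi >= 0.4] = "high"
    return classes.astype(str)


def group_hmi_summary(
    hmi: np.ndarray, groups: dict[str, np.ndarray | set[int]]
) -> dict[str, dict]:
    """Descriptive human-pressure summaries per cell group.

    ``groups`` maps labels (e.g. existing-PA / expansion / non-PA) to cell
    sets or boolean masks that partition the landscape. Empty groups are
    reported with n = 0 rather than dropped.
    """
    hmi = np.asarray(hmi, dtype=float)
    out = {}
    for label, members in groups.items():
        if isinstance(members, (set, frozenset)):
            idx = np.fromiter(members, dtype=int) if members else np.array([], int)
        else:
            idx = np.flatnonzero(np.asarray(members, dtype=bool))
        vals = hmi[idx]
        cls = hmi_classify(vals) if vals.size else np.array([], dtype=str)
        out[label] = {
            "n": int(vals.size),
            "mean": float(vals.mean()) if vals.size else float("nan"),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            "class_shares": {
                c: float((cls == c).mean()) if vals.size else float("nan")
                for c in HMI_CLASSES
            },
        }
    return out


def aoa_novel_climate(
    reference: ClimateStack,
    projection: ClimateStack,
    quantile: float = 0.95,
) -> np.ndarray:
    """Flag projected cells whose climate is novel relative to the reference.

    Variables are standardized by the reference mean/sd. Each projected
    cell's dissimilarity is its nearest-neighbour Euclidean distance to the
    reference cells, scaled by the mean pairwise reference distance; a cell
    is novel when that exceeds the given quantile of the reference cells'
    own leave-one-out dissimilarities (the area-of-applicability rule).
    """
    if reference.var_names != projection.var_names:
        raise ValueError("reference and projection stacks differ in variables")
    if reference.n_cells < 2:
        raise ValueError("need at least 2 reference cells")
    mu = reference.values.mean(axis=0)
    sd = reference.values.std(axis=0)
    sd[sd == 0] = 1.0
    ref = (reference.values - mu) / sd
    proj = (projection.values - mu) / sd
    mean_pair = pdist(ref).mean()
    tree = cKDTree(ref)
    d_loo, _ = tree.query(ref, k=2)
    thresh = np.quantile(d_loo[:, 1] / mean_pair, quantile)
    d_proj, _ = tree.query(proj)
    return (d_proj / mean_pair) > thresh


def expansion_report(
    rank_with_pa_mask: RankMap,
    existing_protected: set[int] | np.ndarray,
    branches: list[BranchFeature],
    pd_classes: np.ndarray,
    add_fractions: tuple[float, ...] = (0.15, 0.35),
) -> dict[float, dict]:
    """Coverage gains from expanding PAs into the top-ranked free cells.

    For each additional landscape fraction, the expansion set is the
    highest-priority free cells of that size (the masked run already pins
    existing PAs to the very top, so the best free cells sit directly below
    them). Reports mean branch coverage and per-PD-class protection before
    and after expansion.
    """
    if isinstance(existing_protected, np.ndarray):
        existing_protected = set(np.flatnonzero(existing_protected).tolist())
    n = rank_with_pa_mask.n_cells
    order = rank_with_pa_mask.removal_order
    free = np.array([c for c in range(n) if c not in existing_protected])
    free_sorted = free[np.argsort(order[free])[::-1]]  # best free cells first
    prot_before = np.zeros(n, dtype=bool)
    prot_before[list(existing_protected)] = True
    before_cov = mean_branch_coverage(branches, existing_protected)
    before_pd = pd_class_protection(pd_classes, prot_before)
    out: dict[float, dict] = {}
    for add in add_fractions:
        k = int(np.ceil(add * n))
        if k > free.size:
            raise ValueError(
                f"additional fraction {add} exceeds the free-cell share")
        expansion = set(free_sorted[:k].tolist())
        prot_after = prot_before.copy()
        prot_after[list(expansion)] = True
        out[add] = {
            "expansion_cells": expansion,
            "coverage_before": before_cov,
            "coverage_after": mean_branch_coverage(
                branches, existing_protected | expansion),
            "pd_class_before": before_pd,
            "pd_class_after": pd_class_protection(pd_classes, prot_after),
        }
    return out
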