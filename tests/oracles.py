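"""Independent reference implementations used to cross-check the package.

These are deliberately written in a different style from the library code
(pure-Python loops over sets and dicts, no shared helpers) so that agreement
is evidence of correctness rather than of shared bugs.
"""

from __future__ import annotations

import numpy as np


def greedy_removal_order(
    feature_cells: list[set[int]],
    weights: list[float],
    n_cells: int,
    rule: str,
    seed: int = 0,
    cost: list[float] | None = None,
    mask: list[int] | None = None,
) -> list[int]:
    """Exhaustive greedy cell removal, recomputing every loss from scratch.

    Returns cell ids in removal order (first removed first). Ties on the
    exact minimum loss are broken by a seeded random choice among the tied
    cells in ascending order, only consuming randomness when a tie occurs.
    """
    cost = cost or [1.0] * n_cells
    mask = mask or [0] * n_cells
    rng = np.random.default_rng(seed)
    remaining = set(range(n_cells))
    order: list[int] = []
    for stratum in (0, 1):
        while True:
            eligible = sorted(c for c in remaining if mask[c] == stratum)
            if not eligible:
                break
            losses = {}
            for i in eligible:
                vals = []
                for j, cells in enumerate(feature_cells):
                    total = len(cells & remaining)
                    if total > 0 and i in cells:
                        vals.append(weights[j] / total)
                if not vals:
                    loss = 0.0
                elif rule == "caz":
                    loss = max(vals) / cost[i]
                else:
                    loss = sum(vals) / cost[i]
                losses[i] = loss
            m = min(losses.values())
            tied = [i for i in eligible if losses[i] == m]
            pick = tied[0] if len(tied) == 1 else int(rng.choice(tied))
            remaining.discard(pick)
            order.append(pick)
    return order


def pd_induced_subtree(tree, species_in_cell: set[str]) -> float:
    """Faith's PD by explicit tip-to-root path union on a dendropy tree."""
    edges = set()
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in species_in_cell:
            continue
        node = leaf
        while node.parent_node is not None:
            if node.edge.length is not None:
                edges.add(node)
            node = node.parent_node
    return float(sum(n.edge.length for n in edges))


def descendant_tips(tree, node) -> set[str]:
    """Brute-force descendant tip labels by recursive enumeration."""
    if node.is_leaf():
        return {node.taxon.label}
    out: set[str] = set()
    for ch in node.child_nodes():
        out |= descendant_tips(tree, ch)
    return out


def point_segment_distance(p, a, b) -> float:
    """Euclidean distance from point p to segment ab (own formula)."""
    p, a, b = (np.asarray(v, dtype=float) for v in (p, a, b))
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return float(np.hypot(*(p - a)))
    t = np.clip(float((p - a) @ ab) / denom, 0.0, 1.0)
    return float(np.hypot(*(p - (a + t * ab))))


def quantile_classes_by_rank(values: np.ndarray, n_classes: int) -> np.ndarray:
    """Rank-based quantile classes with ties pushed to the lower class.

    The class of a value is the smallest class whose cumulative quota
    (ceil(k*n/n_classes) sorted positions) reaches the value's first-
    occurrence rank, so all copies of a tied value share one class.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    srt = np.sort(values)
    classes = np.empty(n, dtype=int)
    for i, v in enumerate(values):
        r = int(np.searchsorted(srt, v, side="left")) + 1  # first-occurrence rank
        for k in range(1, n_classes + 1):
            if int(np.ceil(k * n / n_classes)) >= r:
                classes[i] = k
                break
    return classes
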