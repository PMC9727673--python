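"""Tree-of-life feature layers: branch occurrences, Faith's PD, vulnerability.

A phylogenetic *branch* (the edge above a node) is treated as a conservation
feature: it is present in a grid cell if any of its descendant tips occurs
there, and its weight is its branch length, so protecting the cell protects
that much evolutionary history. Faith's phylogenetic diversity (PD) of a
cell is then the summed length of all branches present in it — equivalently
the length of the subtree connecting the cell's species to the root.
"""

from __future__ import annotations

import hashlib
import logging
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
from dendropy import Tree
from dendropy.simulate import treesim

from .grid import PresenceMatrix
from .sdm import BinaryRange

logger = logging.getLogger(__name__)

__all__ = [
    "BranchFeature",
    "VulnerabilityRecord",
    "graft_and_resolve",
    "branch_occurrences",
    "branch_matrix",
    "faith_pd_per_cell",
    "compute_csh",
    "classify_csh",
    "pd_quantile_classes",
]


def _branch_id(tips: frozenset[str]) -> str:
    """Stable content hash of the descendant tip set (comparable across runs)."""
    h = hashlib.sha1(",".join(sorted(tips)).encode()).hexdigest()
    return h[:12]


@dataclass(frozen=True)
class BranchFeature:
    """One edge of the tree as a spatial conservation feature."""

    branch_id: str
    weight: float           # branch length
    cells: frozenset[int]   # union of descendant tips' occupied cells
    tips: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("branch weight (length) must be positive")


@dataclass(frozen=True)
class VulnerabilityRecord:
    """Relative change in suitable habitat (CSH) of a species or branch."""

    unit_id: str
    current_cells: int
    future_cells: int
    csh: float              # (future - current) / current; nan if current == 0
    label: str              # lost | contracted | stable | greatly_expanded | undefined
    flagged: bool = False


def graft_and_resolve(
    backbone: Tree,
    genus_membership: dict[str, str],
    seed: int = 0,
    birth: float = 1.0,
    death: float = 0.2,
) -> Tree:
    """Expand a genus-level backbone to species level.

    Each genus tip is replaced by its member species; genera with several
    species receive a randomly resolved binary subtree whose topology and
    node heights come from a birth-death simulation rescaled to a crown age
    sampled below the genus stem (so the backbone's ultrametricity is
    preserved for the grafted tips). Species whose genus is not a backbone
    tip are excluded with a logged listing.
    """
    tip_labels = {lf.taxon.label for lf in backbone.leaf_node_iter()}
    unknown = sorted(s for s, g in genus_membership.items() if g not in tip_labels)
    if unknown:
        logger.warning("graft_and_resolve: %d species with unknown genus "
                       "excluded: %s", len(unknown), unknown[:10])
    by_genus: dict[str, list[str]] = {}
    for s, g in sorted(genus_membership.items()):
        if g in tip_labels:
            by_genus.setdefault(g, []).append(s)

    rng = random.Random(seed)
    work = backbone.clone(depth=1)
    ns = work.taxon_namespace
    genus_tips = {lf.taxon.label: lf for lf in work.leaf_node_iter()}
    for genus in sorted(by_genus):
        species = by_genus[genus]
        tip = genus_tips[genus]
        if len(species) == 1:
            tip.taxon = ns.require_taxon(label=species[0])
            continue
        stem = tip.edge.length
        crown = rng.uniform(0.5, 0.9) * stem
        sub = treesim.birth_death_tree(
            birth_rate=birth, death_rate=death,
            num_extant_tips=len(species), rng=rng,
        )
        sub.seed_node.edge.length = None  # stem handled by the graft itself
        depth = max(lf.distance_from_root() for lf in sub.leaf_node_iter())
        # tips born exactly at the stopping time leave zero-length branches
        # (for two species the whole tree degenerates); pad every terminal
        # branch before rescaling so lengths stay positive and ultrametric
        pad = 0.05 * depth if depth > 0 else 1.0
        for lf in sub.leaf_node_iter():
            lf.edge.length += pad
        depth += pad
        scale = crown / depth
        for edge in sub.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
        for lf, sp in zip(sub.leaf_node_iter(), species):
            lf.taxon = ns.require_taxon(label=sp)
        # genus tip becomes the crown node of the grafted subtree
        tip.taxon = None
        tip.edge.length = stem - crown
        for child in list(sub.seed_node.child_nodes()):
            sub.seed_node.remove_child(child)
            tip.add_child(child)
    # reparse for a clean namespace, then drop genera that received no species
    newick = work.as_string(schema="newick", suppress_rooting=True)
    resolved = dendropy.Tree.get(data=newick, schema="newick")
    wanted = {s for members in by_genus.values() for s in members}
    present = {lf.taxon.label for lf in resolved.leaf_node_iter()}
    if present - wanted:
        resolved.retain_taxa_with_labels(sorted(wanted))
    return resolved


def branch_occurrences(tree: Tree, presences: PresenceMatrix
                       ) -> list[BranchFeature]:
    """One feature per edge (root edge excluded): occupied cells are the
    union over descendant tips' occupied cells; weight is branch length."""
    missing = [lf.taxon.label for lf in tree.leaf_node_iter()
               if lf.taxon.label not in set(presences.species)]
    if missing:
        raise ValueError(f"tips without presence rows: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    n_cells = presences.n_cells
    features: list[BranchFeature] = []
    occ_of: dict[int, np.ndarray] = {}
    tips_of: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            occ = presences.occupancy[presences.species.index(label)].copy()
            tips = frozenset([label])
        else:
            occ = np.zeros(n_cells, dtype=bool)
            tips = frozenset()
            for ch in node.child_nodes():
                occ |= occ_of.pop(id(ch))
                tips |= tips_of.pop(id(ch))
        occ_of[id(node)] = occ
        tips_of[id(node)] = tips
        if node.parent_node is not None and node.edge.length is not None:
            features.append(BranchFeature(
                branch_id=_branch_id(tips),
                weight=float(node.edge.length),
                cells=frozenset(np.flatnonzero(occ).tolist()),
                tips=tips,
            ))
    return features


def branch_matrix(features: list[BranchFeature], n_cells: int
                  ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(occurrence bool matrix, weights, branch ids) from branch features."""
    occ = np.zeros((len(features), n_cells), dtype=bool)
    w = np.empty(len(features))
    ids = []
    for j, f in enumerate(features):
        occ[j, list(f.cells)] = True
        w[j] = f.weight
        ids.append(f.branch_id)
    return occ, w, ids


def faith_pd_per_cell(tree: Tree, presences: PresenceMatrix) -> np.ndarray:
    """Faith's PD per grid cell.

    PD(cell) = sum of lengths of branches whose descendant tips reach the
    cell = total length of the subtree connecting the cell's species to the
    root (tip-to-root paths included, so a single-species cell has nonzero
    PD). Empty cells score 0.
    """
    features = branch_occurrences(tree, presences)
    occ, w, _ = branch_matrix(features, presences.n_cells)
    return w @ occ


def compute_csh(
    current: BinaryRange | int,
    future: BinaryRange | int,
    unit_id: str | None = None,
    expand_threshold: float = 0.8,
) -> VulnerabilityRecord:
    """Relative change in suitable habitat between two scenarios.

    csh = (future - current) / current. A unit with no future habitat is
    ``lost``; csh > ``expand_threshold`` is ``greatly_expanded``; negative
    csh (but future > 0) is ``contracted``; otherwise ``stable``. A unit
    with no current habitat has undefined csh and is flagged.
    """
    if isinstance(current, BinaryRange):
        unit_id = unit_id or current.species
        n_cur = len(current.cells)
    else:
        n_cur = int(current)
    n_fut = len(future.cells) if isinstance(future, BinaryRange) else int(future)
    unit_id = unit_id or "?"
    if n_cur == 0:
        return VulnerabilityRecord(unit_id, 0, n_fut, float("nan"),
                                   "undefined", flagged=True)
    csh = (n_fut - n_cur) / n_cur
    return VulnerabilityRecord(unit_id, n_cur, n_fut, csh,
                               classify_csh(csh, n_fut, expand_threshold))


def classify_csh(csh: float, future_cells: int,
                 expand_threshold: float = 0.8) -> str:
    if future_cells == 0:
        return "lost"
    if csh > expand_threshold:
        return "greatly_expanded"
    if csh < 0:
        return "contracted"
    return "stable"


def pd_quantile_classes(pd_values: np.ndarray, n_classes: int = 5) -> np.ndarray:
    """Quantile classes 1..n_classes of near-equal size; ties go to the
    lower class. All-equal input collapses to a single class with a warning."""
    pd_values = np.asarray(pd_values, dtype=float)
    n = pd_values.size
    if np.unique(pd_values).size == 1:
        logger.warning("pd_quantile_classes: all values equal; one class")
        return np.ones(n, dtype=int)
    srt = np.sort(pd_values)
    # upper boundary of class k is the value at rank ceil(k*n/n_classes)
    bounds = srt[[int(np.ceil(k * n / n_classes)) - 1 for k in range(1, n_classes + 1)]]
    classes = np.empty(n, dtype=int)
    for i, v in enumerate(pd_values):
        classes[i] = 1 + int(np.searchsorted(bounds, v, side="left"))
    classes[classes > n_classes] = n_classes
    return classes
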