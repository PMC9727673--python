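"""Suitability modelling and the distribution-map post-processing chain.

The emphasis here is on everything that happens *around* a suitability
model: repeated stratified train/test splits, the true skill statistic
(TSS = sensitivity + specificity - 1), max-TSS binarization, a TSS >= 0.5
quality filter, cell-wise median ensembling, clipping predictions to a
buffered minimum convex polygon (MCP) around the occurrences, and the three
dispersal scenarios (full / limited / none) used to project ranges into a
future climate. The suitability model itself is a single regularized
logistic scorer on the climate predictors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, Point
from sklearn.linear_model import LogisticRegression

from .grid import ClimateStack, LandscapeGrid, PresenceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ModelEvaluation",
    "BinaryRange",
    "TrainTestSplit",
    "split_train_test",
    "sample_pseudo_absences",
    "fit_suitability",
    "compute_tss",
    "maxtss_threshold",
    "filter_models",
    "ensemble_median",
    "clip_to_buffered_mcp",
    "apply_dispersal",
    "min_occurrence_filter",
    "model_species",
]

DISPERSAL_SCENARIOS = ("full", "limited", "none")


@dataclass(frozen=True)
class ModelEvaluation:
    """TSS-based skill of one binarized prediction."""

    sensitivity: float
    specificity: float
    threshold: float = float("nan")
    replicate: int = -1

    @property
    def tss(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass(frozen=True)
class BinaryRange:
    """One species' occupied cell set under a scenario and dispersal label."""

    species: str
    cells: frozenset[int]
    scenario: str = "current"
    dispersal: str = "full"

    def __post_init__(self) -> None:
        if self.dispersal not in DISPERSAL_SCENARIOS:
            raise ValueError(f"unknown dispersal scenario {self.dispersal!r}")
        object.__setattr__(self, "cells", frozenset(int(c) for c in self.cells))


@dataclass(frozen=True)
class TrainTestSplit:
    train_presence: np.ndarray
    test_presence: np.ndarray
    train_absence: np.ndarray
    test_absence: np.ndarray
    replicate: int


def split_train_test(
    presences: np.ndarray,
    absences: np.ndarray,
    train_frac: float = 0.8,
    n_repeats: int = 10,
    seed: int = 0,
) -> list[TrainTestSplit]:
    """Repeated stratified random partitions of presence and absence cells.

    Each repeat partitions both classes independently: ``train_frac`` of the
    presences (rounded) go to training, the rest to testing, likewise for
    absences, so train and test are disjoint and their union is the input.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    presences = np.asarray(presences)
    absences = np.asarray(absences)
    if presences.size < 5:
        raise ValueError("need at least 5 presences to split")
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(n_repeats):
        p = rng.permutation(presences)
        a = rng.permutation(absences)
        np_train = int(round(train_frac * p.size))
        na_train = int(round(train_frac * a.size))
        # keep at least one point on each side of each class
        np_train = min(max(np_train, 1), p.size - 1)
        na_train = min(max(na_train, 1), a.size - 1)
        out.append(TrainTestSplit(
            train_presence=np.sort(p[:np_train]),
            test_presence=np.sort(p[np_train:]),
            train_absence=np.sort(a[:na_train]),
            test_absence=np.sort(a[na_train:]),
            replicate=rep,
        ))
    return out


def sample_pseudo_absences(
    occupied: np.ndarray, n_cells: int, ratio: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Uniform pseudo-absences from unoccupied cells at presence:absence
    ratio 1:``ratio`` (capped by availability)."""
    occupied = np.asarray(occupied)
    pool = np.setdiff1d(np.arange(n_cells), occupied)
    n = min(int(round(ratio * occupied.size)), pool.size)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(pool, size=n, replace=False))


def fit_suitability(
    train_presence: np.ndarray,
    train_absence: np.ndarray,
    predictors: ClimateStack,
    seed: int = 0,
    C: float = 1.0,
) -> np.ndarray:
    """Per-cell suitability in [0, 1] from a regularized logistic scorer.

    Degenerate (zero-variance) predictors yield a constant 0.5 map with a
    logged warning rather than an error, so an uninformative landscape does
    not halt a multi-species run.
    """
    X = predictors.values
    if np.allclose(X.std(axis=0), 0.0):
        logger.warning("fit_suitability: zero-variance predictors; constant map")
        return np.full(X.shape[0], 0.5)
    rows = np.concatenate([train_presence, train_absence])
    y = np.concatenate([np.ones(len(train_presence)), np.zeros(len(train_absence))])
    model = LogisticRegression(C=C, max_iter=1000, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X[rows], y)
    return model.predict_proba(X)[:, 1]


def compute_tss(predicted: np.ndarray, observed: np.ndarray,
                threshold: float = float("nan"), replicate: int = -1) -> ModelEvaluation:
    """True skill statistic of a binary prediction against binary truth.

    Raises if either class is absent from ``observed`` (sensitivity or
    specificity would be undefined).
    """
    predicted = np.asarray(predicted, dtype=bool)
    observed = np.asarray(observed, dtype=bool)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must cover the same cells")
    n_pos = int(observed.sum())
    n_neg = int((~observed).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("observed data must contain both classes")
    tp = int((predicted & observed).sum())
    tn = int((~predicted & ~observed).sum())
    return ModelEvaluation(sensitivity=tp / n_pos, specificity=tn / n_neg,
                           threshold=threshold, replicate=replicate)


def maxtss_threshold(
    scores: np.ndarray, observed: np.ndarray, replicate: int = -1
) -> tuple[float, ModelEvaluation]:
    """Suitability cutoff that maximizes TSS; binarization is score >= cutoff.

    Candidates are all distinct observed scores plus the 0 and 1 endpoints;
    among equal maximizers the smallest cutoff wins. If every score is
    identical, that score is returned with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    if np.unique(scores).size == 1:
        logger.warning("maxtss_threshold: all scores identical")
        t = float(scores[0])
        return t, compute_tss(scores >= t, observed, threshold=t, replicate=replicate)
    candidates = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    best_t, best_eval = None, None
    for t in candidates:  # ascending, so first max is the smallest maximizer
        ev = compute_tss(scores >= t, observed, threshold=float(t), replicate=replicate)
        if best_eval is None or ev.tss > best_eval.tss + 1e-12:
            best_t, best_eval = float(t), ev
    return best_t, best_eval


def filter_models(evals: list[ModelEvaluation], min_tss: float = 0.5
                  ) -> list[ModelEvaluation]:
    """Retain evaluations with TSS >= ``min_tss`` (inclusive)."""
    kept = [e for e in evals if e.tss >= min_tss]
    if not kept:
        logger.info("filter_models: no model reached TSS >= %.2f", min_tss)
    return kept


def ensemble_median(maps: list[np.ndarray]) -> np.ndarray:
    """Cell-wise median across suitability maps (mean of the middle pair
    when the count is even)."""
    if not maps:
        raise ValueError("need at least one map to ensemble")
    arr = np.asarray(maps, dtype=float)
    if arr.ndim != 2:
        raise ValueError("maps must share one grid")
    return np.median(arr, axis=0)


def clip_to_buffered_mcp(
    rng: BinaryRange,
    occurrences: np.ndarray,
    grid: LandscapeGrid,
    buffer_km: float = 200.0,
) -> BinaryRange:
    """Drop predicted presences outside the buffered minimum convex polygon
    of the occurrence cell centres.

    With one or two occurrences the hull degrades to a buffered point or
    segment. Distances are planar Euclidean in km on the equal-area grid.
    """
    occurrences = np.asarray(occurrences)
    if occurrences.size == 0:
        raise ValueError("cannot clip to an empty occurrence set")
    pts = MultiPoint(grid.coords[occurrences].tolist())
    hull = pts.convex_hull.buffer(buffer_km)
    kept = frozenset(
        c for c in rng.cells if hull.covers(Point(grid.x[c], grid.y[c]))
    )
    return BinaryRange(rng.species, kept, rng.scenario, rng.dispersal)


def apply_dispersal(
    current: BinaryRange,
    future_unconstrained: BinaryRange,
    scenario: str,
    grid: LandscapeGrid,
    buffer_km: float = 200.0,
) -> BinaryRange:
    """Constrain a projected future range by dispersal ability.

    full    -> unchanged;
    none    -> future ∩ current (no colonization);
    limited -> future ∩ {cells within ``buffer_km`` of the current range}
               (e.g. 200 km = 20 km per decade over a century).
    """
    if current.species != future_unconstrained.species:
        raise ValueError("current and future ranges are for different species")
    if scenario == "full":
        cells = future_unconstrained.cells
    elif scenario == "none":
        cells = future_unconstrained.cells & current.cells
    elif scenario == "limited":
        cur = np.fromiter(current.cells, dtype=int)
        if cur.size == 0:
            cells = frozenset()
        else:
            tree = cKDTree(grid.coords[cur])
            fut = np.fromiter(future_unconstrained.cells, dtype=int)
            d, _ = tree.query(grid.coords[fut])
            cells = frozenset(fut[d <= buffer_km].tolist())
    else:
        raise ValueError(f"unknown dispersal scenario {scenario!r}")
    return BinaryRange(current.species, cells,
                       future_unconstrained.scenario, scenario)


def min_occurrence_filter(presences: PresenceMatrix, min_occ: int = 20
                          ) -> PresenceMatrix:
    """Drop species occupying fewer than ``min_occ`` cells (inclusive keep)."""
    sizes = presences.range_sizes()
    keep = [s for s, n in zip(presences.species, sizes) if n >= min_occ]
    dropped = presences.n_species - len(keep)
    if dropped:
        logger.info("min_occurrence_filter: removed %d species below %d cells",
                    dropped, min_occ)
    return presences.subset(keep)


@dataclass
class SpeciesModelResult:
    """Ensembled, clipped, dispersal-constrained ranges for one species."""

    species: str
    evaluations: list[ModelEvaluation]
    retained: int
    threshold: float
    current: BinaryRange | None
    future: dict[str, BinaryRange]   # dispersal label -> range

    @property
    def modellable(self) -> bool:
        return self.current is not None


def model_species(
    species: str,
    occupied: np.ndarray,
    climate: ClimateStack,
    future_climate: ClimateStack,
    grid: LandscapeGrid,
    seed: int = 0,
    n_repeats: int = 10,
    train_frac: float = 0.8,
    min_tss: float = 0.5,
    absence_ratio: float = 1.0,
    buffer_km: float = 200.0,
) -> SpeciesModelResult:
    """Full single-species modelling chain.

    Pseudo-absences are sampled uniformly from unoccupied cells; models are
    fit on repeated 80/20 splits and scored by TSS on held-out cells; models
    with TSS >= ``min_tss`` are median-ensembled; the ensemble is binarized
    at its max-TSS threshold, clipped to the buffered MCP of the
    occurrences, and projected to the future climate under all three
    dispersal scenarios. Species with no retained model are flagged
    unmodellable (``current is None``).
    """
    occupied = np.asarray(occupied)
    absences = sample_pseudo_absences(occupied, grid.n_cells, absence_ratio, seed)
    splits = split_train_test(occupied, absences, train_frac, n_repeats, seed + 1)
    observed = np.zeros(grid.n_cells, dtype=bool)
    observed[occupied] = True

    evals = []
    for sp in splits:
        suit = fit_suitability(sp.train_presence, sp.train_absence, climate, seed)
        test_cells = np.concatenate([sp.test_presence, sp.test_absence])
        t, _ = maxtss_threshold(suit[test_cells], observed[test_cells])
        ev = compute_tss(suit[test_cells] >= t, observed[test_cells],
                         threshold=t, replicate=sp.replicate)
        evals.append(ev)
    retained_idx = [i for i, e in enumerate(evals) if e.tss >= min_tss]
    if not retained_idx:
        logger.info("model_species: %s unmodellable (max TSS %.2f)", species,
                    max(e.tss for e in evals))
        return SpeciesModelResult(species, evals, 0, float("nan"), None, {})

    # refit retained replicates once to project onto both climates
    cur_maps, fut_maps = [], []
    for i in retained_idx:
        sp = splits[i]
        rows = np.concatenate([sp.train_presence, sp.train_absence])
        y = np.concatenate([np.ones(sp.train_presence.size),
                            np.zeros(sp.train_absence.size)])
        model = LogisticRegression(C=1.0, max_iter=1000, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(climate.values[rows], y)
        cur_maps.append(model.predict_proba(climate.values)[:, 1])
        fut_maps.append(model.predict_proba(future_climate.values)[:, 1])

    ens_cur = ensemble_median(cur_maps)
    ens_fut = ensemble_median(fut_maps)
    thr, _ = maxtss_threshold(ens_cur, observed)
    current = BinaryRange(species, frozenset(np.flatnonzero(ens_cur >= thr).tolist()),
                          scenario="current")
    current = clip_to_buffered_mcp(current, occupied, grid, buffer_km)
    fut_full = BinaryRange(species, frozenset(np.flatnonzero(ens_fut >= thr).tolist()),
                           scenario=future_climate.scenario)
    future = {
        d: apply_dispersal(current, fut_full, d, grid, buffer_km)
        for d in DISPERSAL_SCENARIOS
    }
    return SpeciesModelResult(species, evals, len(retained_idx), thr, current, future)
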