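"""Seeded synthetic landscapes for exercising the prioritization pipeline.

The generators emulate the statistical structure the downstream analysis
assumes, without any real-world data:

* spatially autocorrelated, standardized climate surfaces and shifted
  "future" counterparts;
* an ultrametric birth-death phylogeny;
* species ranges carved from Gaussian climatic niches whose optima evolve
  on the tree by Brownian motion, so closely related species have correlated
  ranges and phylogenetic diversity has spatial structure;
* a right-skewed range-size distribution with a minimum-occurrence floor;
* a spatially clustered protected-area (PA) mask biased away from
  high-human-pressure cells, and a human modification index (HMI) surface
  correlated with a designated (warm/lowland proxy) climate variable.

Every generator is a pure function of its arguments including ``seed``.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import numpy as np
from dendropy import Tree
from dendropy.simulate import treesim
from scipy.ndimage import gaussian_filter

from .grid import ClimateStack, LandscapeGrid, PresenceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "simulate_climate",
    "shift_climate",
    "simulate_tree",
    "simulate_ranges",
    "simulate_pa_and_hmi",
    "simulate_landscape",
    "morans_i",
]

#: six bioclimatic-style variable names used when n_vars == 6
_BIOCLIM_NAMES = ("bio4", "bio10", "bio11", "bio15", "bio16", "bio17")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic landscape; defaults give a desk-scale study.

    The grid is 30 x 30 cells of 20 x 20 km (400 km² each) and carries 150
    species, enough for the full pipeline to run in minutes on one CPU while
    keeping hundreds of phylogenetic branches as prioritization features.
    """

    n_species: int = 150
    nx: int = 30
    ny: int = 30
    cell_size_km: float = 20.0
    n_env_vars: int = 6
    corr_len: float = 6.0          # climate autocorrelation length, cells
    birth: float = 1.0             # speciation rate (per lineage per unit time)
    death: float = 0.2             # extinction rate
    niche_rate: float = 0.5        # Brownian sd of niche optima per unit time
    niche_breadth: float = 0.7     # Gaussian niche sd in standardized env units
    threshold: float = 0.55       # suitability cutoff for presence
    min_occ: int = 20              # minimum occupied cells to retain a species
    max_resample: int = 10         # niche redraws before dropping a species
    # warming-dominated future shift (sd units): temperature-side variables
    # move most, precipitation-side variables little
    climate_shift: tuple[float, ...] | float = (0.4, 0.3, 0.3, 0.1, 0.0, -0.1)
    shift_noise_sd: float = 0.1
    pa_fraction: float = 0.15      # target share of protected cells
    pa_bias: float = 1.0           # strength of PA placement away from high HMI
    seed: int = 0

    def __post_init__(self) -> None:
        if self.birth <= self.death or self.death < 0:
            raise ValueError("require birth > death >= 0")
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if not 0 <= self.pa_fraction <= 1:
            raise ValueError("pa_fraction must be in [0, 1]")
        if not 0 <= self.pa_bias <= 1:
            raise ValueError("pa_bias must be in [0, 1]")
        if self.niche_rate < 0:
            raise ValueError("niche_rate must be non-negative")
        if (isinstance(self.climate_shift, tuple)
                and len(self.climate_shift) != self.n_env_vars):
            raise ValueError("climate_shift length must match n_env_vars")


def _lattice_shape(grid: LandscapeGrid) -> tuple[int, int]:
    if grid.shape is None:
        raise ValueError("climate simulation requires a regular lattice grid")
    return grid.shape


def simulate_climate(
    grid: LandscapeGrid,
    n_vars: int = 6,
    corr_len: float = 6.0,
    seed: int = 0,
    scenario: str = "current",
) -> ClimateStack:
    """Zero-mean unit-variance spatially autocorrelated climate surfaces.

    Each variable is Gaussian-smoothed white noise, re-standardized after
    smoothing. ``corr_len`` is the structure scale in cells; ``corr_len=1``
    means no smoothing (independent cells). Kernel sigma is
    ``(corr_len - 1)/2`` so neighbouring-cell correlation rises smoothly
    from ~0.
    """
    if corr_len < 1:
        raise ValueError("corr_len must be >= 1 cell")
    ny, nx = _lattice_shape(grid)
    rng = np.random.default_rng(seed)
    sigma = 0.5 * (corr_len - 1.0)
    cols = []
    for _ in range(n_vars):
        f = rng.standard_normal((ny, nx))
        if sigma > 0:
            f = gaussian_filter(f, sigma=sigma, mode="reflect")
        f = (f - f.mean()) / f.std()
        cols.append(f.ravel())
    names = _BIOCLIM_NAMES if n_vars == 6 else tuple(f"env{i+1}" for i in range(n_vars))
    return ClimateStack(np.column_stack(cols), names, scenario=scenario)


def shift_climate(
    climate: ClimateStack,
    shift: tuple[float, ...] | float,
    noise_sd: float = 0.1,
    seed: int = 0,
    name: str = "future",
) -> ClimateStack:
    """Future scenario: current values plus a constant per-variable shift
    and small independent cell noise."""
    shift_vec = np.broadcast_to(np.asarray(shift, dtype=float), (climate.n_vars,))
    rng = np.random.default_rng(seed)
    values = climate.values + shift_vec + noise_sd * rng.standard_normal(climate.values.shape)
    return ClimateStack(values, climate.var_names, scenario=f"future-{name}")


def simulate_tree(n_species: int, birth: float = 1.0, death: float = 0.2,
                  seed: int = 0) -> Tree:
    """Ultrametric birth-death tree with ``n_species`` extant tips.

    Terminal branches are extended by a small constant (1% of mean tip depth)
    so that tips born exactly at the stopping time do not leave zero-length
    branches; ultrametricity is preserved.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if not birth > death >= 0:
        raise ValueError("require birth > death >= 0")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth, death_rate=death, num_extant_tips=n_species, rng=rng
    )
    depth = np.mean([lf.distance_from_root() for lf in tree.leaf_node_iter()])
    eps = 0.01 * depth
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += eps
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i:04d}"
    tree.seed_node.edge.length = None
    return tree


def _suitability(env: np.ndarray, opt: np.ndarray, breadth: float) -> np.ndarray:
    """Gaussian niche suitability in [0, 1], dimension-normalized."""
    d2 = ((env - opt) ** 2).mean(axis=1)
    return np.exp(-0.5 * d2 / breadth**2)


def simulate_ranges(
    tree: Tree,
    climate: ClimateStack,
    niche_rate: float = 0.5,
    threshold: float = 0.55,
    min_occ: int = 20,
    seed: int = 0,
    niche_breadth: float = 0.7,
    max_resample: int = 10,
) -> tuple[PresenceMatrix, dict[str, np.ndarray]]:
    """Species ranges from niches that evolve on the tree.

    A species occupies every cell where its Gaussian suitability is at least
    ``threshold``. Species whose range falls below ``min_occ`` cells have
    their tip optimum redrawn (from the parent node's optimum) up to
    ``max_resample`` times, then are dropped with a logged count; this keeps
    the occurrence floor from silently pruning whole clades.

    Returns the presence matrix of retained species and the per-species
    niche optima actually used.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    env = climate.values
    rng = np.random.default_rng(seed)
    optima: dict[int, np.ndarray] = {id(tree.seed_node): np.zeros(climate.n_vars)}
    tips: dict[str, np.ndarray] = {}
    parent_opt: dict[str, np.ndarray] = {}
    stem_len: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = optima[id(node.parent_node)]
        sd = niche_rate * np.sqrt(node.edge.length)
        opt = parent + sd * rng.standard_normal(climate.n_vars)
        optima[id(node)] = opt
        if node.is_leaf():
            tips[node.taxon.label] = opt
            parent_opt[node.taxon.label] = parent
            stem_len[node.taxon.label] = node.edge.length

    species = [lf.taxon.label for lf in tree.leaf_node_iter()]
    occ_rows, kept, used_opt = [], [], {}
    n_dropped = 0
    for i, sp in enumerate(species):
        opt = tips[sp]
        row = _suitability(env, opt, niche_breadth) >= threshold
        tries = 0
        sp_rng = np.random.default_rng((seed, i))
        while row.sum() < min_occ and tries < max_resample:
            sd = niche_rate * np.sqrt(stem_len[sp]) if niche_rate > 0 else 0.0
            opt = parent_opt[sp] + sd * sp_rng.standard_normal(climate.n_vars)
            row = _suitability(env, opt, niche_breadth) >= threshold
            tries += 1
        if row.sum() < min_occ:
            n_dropped += 1
            continue
        occ_rows.append(row)
        kept.append(sp)
        used_opt[sp] = opt
    if n_dropped:
        logger.info("simulate_ranges: dropped %d species below min_occ=%d",
                    n_dropped, min_occ)
    if not kept:
        raise ValueError("no species met the minimum-occurrence floor")
    return PresenceMatrix(np.array(occ_rows), kept), used_opt


def simulate_pa_and_hmi(
    grid: LandscapeGrid,
    climate: ClimateStack,
    pa_fraction: float = 0.15,
    pa_bias: float = 1.0,
    seed: int = 0,
    hmi_var: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Protected-area fractions and a human-pressure surface.

    HMI is a [0, 1] surface positively correlated with a designated climate
    variable (a warm/lowland proxy; defaults to the first variable) — human
    pressure concentrates in warm lowlands. PA cover is placed on a smooth
    score field; ``pa_bias`` pushes the score away from high-HMI cells, so at
    ``pa_bias=1`` protection clusters in the least modified landscapes, the
    historical pattern of reserve placement. Selected cells receive a PA area
    fraction in (0.5, 1], so the realized share of protected cells at the
    30% cutoff equals ``pa_fraction`` up to rounding.
    """
    if not 0 <= pa_fraction <= 1 or not 0 <= pa_bias <= 1:
        raise ValueError("pa_fraction and pa_bias must be in [0, 1]")
    ny, nx = _lattice_shape(grid)
    rng = np.random.default_rng(seed)

    driver = climate.var(hmi_var) if hmi_var else climate.values[:, 0]
    noise = gaussian_filter(rng.standard_normal((ny, nx)), sigma=2.0,
                            mode="reflect").ravel()
    raw = 0.7 * driver + 0.3 * (noise - noise.mean()) / noise.std()
    # rank-to-uniform then square: right-skewed like real human-pressure maps
    u = (np.argsort(np.argsort(raw)) + 0.5) / raw.size
    hmi = u**2

    n_pa = int(round(pa_fraction * grid.n_cells))
    pa = np.zeros(grid.n_cells)
    if n_pa > 0:
        smooth = gaussian_filter(rng.standard_normal((ny, nx)), sigma=3.0,
                                 mode="reflect").ravel()
        z_hmi = (hmi - hmi.mean()) / hmi.std()
        score = (smooth - smooth.mean()) / smooth.std() - 2.0 * pa_bias * z_hmi
        chosen = np.argsort(score)[-n_pa:]
        pa[chosen] = rng.uniform(0.5, 1.0, size=n_pa)
    return pa, hmi


@dataclass
class SyntheticLandscape:
    """Bundle of every synthetic layer produced from one config + seed."""

    config: SimulationConfig
    grid: LandscapeGrid
    climate: ClimateStack
    future_climate: ClimateStack
    tree: Tree
    presences: PresenceMatrix
    niche_optima: dict[str, np.ndarray] = field(repr=False)
    pa_fraction: np.ndarray = field(repr=False)
    hmi: np.ndarray = field(repr=False)


def simulate_landscape(config: SimulationConfig) -> SyntheticLandscape:
    """Generate the complete landscape a single pipeline run consumes.

    Per-stage seeds are derived deterministically from ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed).spawn(5)
    seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss]
    grid = LandscapeGrid.regular(config.nx, config.ny, config.cell_size_km)
    climate = simulate_climate(grid, config.n_env_vars, config.corr_len, seeds[0])
    future = shift_climate(climate, config.climate_shift, config.shift_noise_sd,
                           seeds[1])
    tree = simulate_tree(config.n_species, config.birth, config.death, seeds[2])
    presences, optima = simulate_ranges(
        tree, climate, config.niche_rate, config.threshold, config.min_occ,
        seeds[3], config.niche_breadth, config.max_resample,
    )
    pa, hmi = simulate_pa_and_hmi(grid, climate, config.pa_fraction,
                                  config.pa_bias, seeds[4])
    retained = set(presences.species)
    tree = tree.clone(depth=1)
    tree.retain_taxa_with_labels(sorted(retained))
    return SyntheticLandscape(config, grid, climate, future, tree, presences,
                              optima, pa, hmi)


def morans_i(values: np.ndarray, grid: LandscapeGrid) -> float:
    """Lag-1 (rook neighbours) Moran's I of a per-cell field on the lattice."""
    ny, nx = _lattice_shape(grid)
    z = np.asarray(values, dtype=float).reshape(ny, nx)
    z = z - z.mean()
    num = (z[:, :-1] * z[:, 1:]).sum() + (z[:-1, :] * z[1:, :]).sum()
    w = (ny * (nx - 1)) + ((ny - 1) * nx)
    return float((z.size / (2 * w)) * (2 * num) / (z**2).sum())
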