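"""Seeded generators for phylogenies, occurrence stacks, and tenure masks.

These emulate the inputs the analysis consumes in the field: a clade's
phylogeny, one species-distribution-model probability raster per tip,
and an integer land-tenure raster. Trees come from a pure-birth (Yule)
process. Species ranges are isotropic Gaussian occurrence surfaces —
a range centre, a decay width, a peak probability — optionally with
phylogenetic signal: range centres evolve by Brownian motion along the
tree, so close relatives have overlapping ranges and internal-branch
layers show realistic nestedness. Tenure masks partition the grid into
levels (cleared / unprotected vegetation / development zone / protected
zone) as contiguous seeded-growth regions or as random cells.

Everything is fully determined by the config seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np
from dendropy.model import birthdeath

from .landscape import GridSpec, MaskGrid, RasterStack

__all__ = [
    "SimulationConfig",
    "simulate_phylogeny",
    "simulate_occurrences",
    "simulate_tenure",
    "simulate_landscape",
]


def _default_tenure() -> dict:
    # ~60% cleared land; of the remaining vegetation a bit under half sits
    # in parks, split between development-open and fully protected zones
    return {0: 0.60, 1: 0.23, 2: 0.09, 3: 0.08}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic landscape, fixed by one seed.

    n_species/grid defaults (15 species on 30×30) give a landscape small
    enough for exhaustive checking but rich enough that rankings
    meaningfully beat random selection. ``p_max`` = 0.9 keeps peak
    occurrence below certainty as real distribution models do;
    ``range_width_frac`` = 0.15 of the short grid side gives ranges that
    overlap within clades but do not blanket the landscape.
    """

    n_species: int = 15
    n_rows: int = 30
    n_cols: int = 30
    seed: int = 0
    birth_rate: float = 1.0
    p_max: float = 0.9
    range_width_frac: float = 0.15
    range_width_log_sd: float = 0.4
    phylo_signal: bool = True
    prevalence: Optional[float] = None
    tenure_fractions: dict = field(default_factory=_default_tenure)
    tenure_contiguous: bool = True

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if not 0 <= self.p_max <= 1:
            raise ValueError("p_max must be in [0, 1]")
        fracs = list(self.tenure_fractions.values())
        if any(f < 0 for f in fracs):
            raise ValueError("tenure fractions must be >= 0")
        if sum(fracs) > 1 + 1e-9:
            raise ValueError("tenure fractions must sum to <= 1")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols)


def simulate_phylogeny(config: SimulationConfig) -> dendropy.Tree:
    """Pure-birth tree with ``n_species`` tips and positive branch lengths.

    The birth–death simulator stops at the instant of the final
    speciation, which leaves that cherry with zero-length tips; by
    memorylessness the process is continued for one Exp(nλ) interval,
    added to every tip edge, so all branch lengths are positive.
    """
    rng = random.Random(config.seed)
    tree = birthdeath.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=0.0,
        num_extant_tips=config.n_species,
        rng=rng,
    )
    extra = rng.expovariate(config.n_species * config.birth_rate)
    leaves = [lf for lf in tree.leaf_node_iter()]
    for k, leaf in enumerate(leaves):
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
        leaf.taxon.label = f"sp{k + 1:02d}"
    tree.is_rooted = True
    if tree.seed_node.edge.length:
        tree.seed_node.edge.length = None  # root edge carries no feature
    return tree


def _brownian_centers(
    tree: dendropy.Tree, rng: np.random.Generator
) -> dict:
    """Tip (y, x) positions from 2-D unit-rate Brownian motion on the tree."""
    pos = {tree.seed_node: np.zeros(2)}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        step = rng.normal(0.0, np.sqrt(max(nd.edge.length, 0.0)), size=2)
        pos[nd] = pos[nd.parent_node] + step
    return {lf.taxon.label: pos[lf] for lf in tree.leaf_node_iter()}


def simulate_occurrences(
    tree: dendropy.Tree, config: SimulationConfig
) -> RasterStack:
    """One Gaussian occurrence surface per tip species.

    P(cell) = p_max · exp(−d² / 2σ²) with d the distance from the range
    centre and σ the species' drawn range width. With phylogenetic
    signal on, centres follow Brownian motion along the tree (rescaled
    to span the central 70% of the grid); otherwise they are uniform.
    An optional prevalence target rescales each layer's mean.
    """
    if min(config.n_rows, config.n_cols) < 3:
        raise ValueError("grid too small for the requested species ranges")
    rng = np.random.default_rng([config.seed, 1])
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) == 0:
        raise ValueError("tree has no labelled tips")
    dims = np.array([config.n_rows, config.n_cols], dtype=float)

    width_mu = np.log(config.range_width_frac * min(config.n_rows, config.n_cols))
    widths = rng.lognormal(width_mu, config.range_width_log_sd, size=len(labels))

    if config.phylo_signal:
        raw = _brownian_centers(tree, rng)
        pts = np.array([raw[l] for l in labels])
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        span = np.where(hi - lo > 0, hi - lo, 1.0)
        centers = 0.15 * dims + (pts - lo) / span * 0.7 * dims
    else:
        centers = rng.uniform(0.1, 0.9, size=(len(labels), 2)) * dims

    rows, cols = np.meshgrid(
        np.arange(config.n_rows), np.arange(config.n_cols), indexing="ij"
    )
    layers = np.empty((len(labels), config.n_rows * config.n_cols))
    for k in range(len(labels)):
        d2 = (rows - centers[k, 0]) ** 2 + (cols - centers[k, 1]) ** 2
        surf = config.p_max * np.exp(-d2 / (2.0 * widths[k] ** 2))
        if config.prevalence is not None:
            mean = surf.mean()
            if mean <= 0:
                raise ValueError("cannot rescale an all-zero layer to a prevalence")
            surf = surf * (config.prevalence / mean)
            if surf.max() > 1 + 1e-9:
                raise ValueError(
                    f"prevalence {config.prevalence} forces probabilities above 1 "
                    f"for species {labels[k]}"
                )
            surf = np.clip(surf, 0.0, 1.0)
        layers[k] = surf.reshape(-1)
    valid = np.ones(config.n_rows * config.n_cols, dtype=bool)
    return RasterStack(config.grid, list(labels), layers, valid)


def _neighbors(flat: int, grid: GridSpec) -> list:
    r, c = divmod(flat, grid.n_cols)
    out = []
    if r > 0:
        out.append(flat - grid.n_cols)
    if r < grid.n_rows - 1:
        out.append(flat + grid.n_cols)
    if c > 0:
        out.append(flat - 1)
    if c < grid.n_cols - 1:
        out.append(flat + 1)
    return out


def simulate_tenure(config: SimulationConfig, grid: Optional[GridSpec] = None) -> MaskGrid:
    """Partition the grid into tenure levels with target area fractions.

    Cell counts per level are exact (largest-remainder rounding; any
    fraction shortfall tops up level 0), so realized fractions are
    within one cell of the targets. With ``tenure_contiguous`` the
    levels grow as connected regions from random seed cells (jumping to
    a fresh cell only when walled in); otherwise cells are assigned at
    random.
    """
    grid = grid or config.grid
    rng = np.random.default_rng([config.seed, 2])
    levels = sorted(int(l) for l in config.tenure_fractions)
    fracs = np.array([config.tenure_fractions[l] for l in levels], dtype=float)
    n = grid.n_cells
    exact = fracs * n
    counts = np.floor(exact).astype(int)
    shortfall = int(round(fracs.sum() * n)) - counts.sum()
    for idx in np.argsort(-(exact - counts))[:shortfall]:
        counts[idx] += 1
    leftover = n - counts.sum()
    if leftover:
        if 0 not in levels:
            levels = [0] + levels
            counts = np.concatenate([[leftover], counts])
        else:
            counts[levels.index(0)] += leftover
    if (counts < 0).any() or counts.sum() != n:
        raise ValueError("infeasible tenure fractions for this grid")

    assigned = np.full(n, -1, dtype=int)
    if not config.tenure_contiguous:
        perm = rng.permutation(n)
        start = 0
        for lvl, cnt in zip(levels, counts):
            assigned[perm[start : start + cnt]] = lvl
            start += cnt
    else:
        quota = {lvl: int(cnt) for lvl, cnt in zip(levels, counts)}
        frontier: dict = {lvl: [] for lvl in levels}
        active = [lvl for lvl in levels if quota[lvl] > 0]
        while active:
            for lvl in list(active):
                fr = frontier[lvl]
                cell = -1
                while fr:
                    pick = int(rng.integers(len(fr)))
                    cand = fr.pop(pick)
                    if assigned[cand] < 0:
                        cell = cand
                        break
                if cell < 0:
                    unassigned = np.flatnonzero(assigned < 0)
                    cell = int(unassigned[rng.integers(len(unassigned))])
                assigned[cell] = lvl
                quota[lvl] -= 1
                if quota[lvl] == 0:
                    active.remove(lvl)
                fr.extend(
                    nb for nb in _neighbors(cell, grid) if assigned[nb] < 0
                )
    return MaskGrid(grid, assigned, declared_levels=tuple(levels))


def simulate_landscape(config: SimulationConfig):
    """One-shot: (tree, species occurrence stack, tenure mask)."""
    tree = simulate_phylogeny(config)
    species = simulate_occurrences(tree, config)
    mask = simulate_tenure(config, species.grid)
    return tree, species, mask
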