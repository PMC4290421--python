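"""Propagate species occurrence probabilities to every phylogeny branch.

A branch "occurs" in a grid cell if at least one of its descendant
species occurs there. Treating species occurrences within a cell as
independent, the occurrence probability of branch i in cell j is the
union probability

    B_ij = 1 − Π_n (1 − P_nj)

over the branch's m descendant species with per-cell probabilities P_nj.
Tip branches are their species layers verbatim. The product is evaluated
in log-complement space (sum of log1p(−P)) so that probabilities very
close to 1 do not suffer catastrophic cancellation; P = 1 correctly
forces B = 1.

No dependence structure between species is modelled: the independence
assumption is part of the method, not an approximation knob.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .landscape import RasterStack
from .phylogeny import BranchTable

__all__ = ["BranchStack", "branch_probability", "build_branch_stack"]


def branch_probability(tip_probs: Union[Sequence[float], np.ndarray]) -> float:
    """Union probability that any of several independent events occurs.

    ``tip_probs`` are the per-species occurrence probabilities of one
    branch's descendants in one cell; each must lie in [0, 1]. With a
    single descendant the input is returned unchanged.
    """
    p = np.asarray(tip_probs, dtype=float)
    if p.size == 0:
        raise ValueError("empty probability vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    if p.size == 1:
        return float(p.reshape(-1)[0])
    with np.errstate(divide="ignore"):
        log_none = np.sum(np.log1p(-p))
    return float(-np.expm1(log_none))


@dataclass
class BranchStack:
    """Per-branch occurrence-probability layers with branch-length weights.

    A :class:`~phylozone.landscape.RasterStack` whose layer ids are the
    string forms of branch ids, paired with the branch table that defines
    lengths (the default prioritization weights) and descendant sets.
    """

    stack: RasterStack
    table: BranchTable

    def __post_init__(self) -> None:
        expected = [str(b.branch_id) for b in self.table]
        if self.stack.layer_ids != expected:
            raise ValueError("branch stack layers must match branch table ids")

    @property
    def grid(self):
        return self.stack.grid

    @property
    def values(self) -> np.ndarray:
        return self.stack.values

    @property
    def valid_mask(self) -> np.ndarray:
        return self.stack.valid_mask

    @property
    def lengths(self) -> np.ndarray:
        return np.array([b.length for b in self.table], dtype=float)

    def layer(self, branch_id: int) -> np.ndarray:
        return self.stack.layer(str(branch_id))


def build_branch_stack(species: RasterStack, branches: BranchTable) -> BranchStack:
    """Compute one occurrence layer per branch from the species stack.

    Tip-branch layers are copied bitwise from the corresponding species
    layers; internal branches take the union probability over their
    descendant tips, cell by cell. NoData cells stay NoData in every
    branch layer (the species stack already shares one valid mask).
    """
    tip_index = {lid: k for k, lid in enumerate(species.layer_ids)}
    missing = [t for t in branches.tip_labels if t not in tip_index]
    if missing:
        raise ValueError(f"species stack lacks layers for tips: {missing}")

    valid = species.valid_mask
    sp = species.values  # (n_species, n_cells), NaN outside valid
    with np.errstate(divide="ignore", invalid="ignore"):
        log_absent = np.log1p(-sp)  # -inf where P == 1

    n_cells = species.grid.n_cells
    out = np.full((len(branches), n_cells), np.nan)
    for k, br in enumerate(branches):
        if br.is_tip:
            out[k] = sp[tip_index[next(iter(br.descendant_tips))]]
        else:
            rows = [tip_index[t] for t in sorted(br.descendant_tips)]
            with np.errstate(invalid="ignore"):
                b = -np.expm1(log_absent[rows].sum(axis=0))
            out[k, valid] = np.clip(b[valid], 0.0, 1.0)
    raster = RasterStack(
        species.grid, [str(b.branch_id) for b in branches], out, valid.copy()
    )
    return BranchStack(raster, branches)
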