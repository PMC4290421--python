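"""Evaluate rankings and tenure configurations by PD retention.

The central statistic is the proportion of phylogenetic diversity
remaining when only a subset q of the landscape's Q cells is kept:

    PD_remaining = [ Σ_i L_i · ( Σ_{j∈q} B_ij / Σ_{j∈Q} B_ij ) ] / Σ_i L_i

— each branch contributes the fraction of its spatial distribution that
survives, weighted by its length L_i, normalized by total PD. With the
whole landscape kept every branch is fully represented and the statistic
is exactly 1; with nothing kept it is 0.

Denominator conventions matter and are carried as metadata: retention
curves and protected-PD default to Q = the analyzable (e.g. currently
vegetated) cells, while per-branch tenure summaries default to the full
modelled distribution including cleared (level-0) cells, so that a
species whose range was mostly cleared shows up as poorly protected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .branch_propagation import BranchStack
from .landscape import MaskGrid
from .phylogeny import BranchTable
from .prioritization import PriorityResult

__all__ = [
    "PDCurve",
    "TenureSummary",
    "ScenarioReport",
    "pd_retention",
    "pd_curve",
    "protected_pd",
    "expansion_scenario",
    "tenure_summary",
]

VULNERABILITY_CLASSES = ("outside_parks", "lt_1pct", "1_to_5pct", "gt_5pct")


def _as_cell_mask(cells, n_cells: int) -> np.ndarray:
    cells = np.asarray(cells)
    if cells.dtype == bool:
        if cells.shape != (n_cells,):
            raise ValueError("boolean cell mask has wrong length")
        return cells
    mask = np.zeros(n_cells, dtype=bool)
    mask[cells.astype(np.int64)] = True
    return mask


def _branch_totals(
    branches: BranchStack, base_mask: np.ndarray, on_zero: str
) -> tuple:
    vals = np.nan_to_num(branches.values, nan=0.0)
    T = vals[:, base_mask].sum(axis=1)
    keep = np.ones(len(T), dtype=bool)
    if (T <= 0).any():
        zero_ids = [b.branch_id for b, t in zip(branches.table, T) if t <= 0]
        if on_zero == "drop":
            warnings.warn(
                f"dropping {len(zero_ids)} branch(es) with zero total "
                f"representation: {zero_ids}",
                stacklevel=3,
            )
            keep = T > 0
        else:
            raise ValueError(
                f"branch(es) with zero total representation: {zero_ids}; "
                "their remaining fraction is undefined (pass on_zero='drop' "
                "to exclude them with a warning)"
            )
    return vals, T, keep


def pd_retention(
    remaining_cells: Union[np.ndarray, Sequence[int]],
    branches: BranchStack,
    table: Optional[BranchTable] = None,
    base_cells: Optional[np.ndarray] = None,
    on_zero: str = "error",
) -> float:
    """Proportion of PD remaining on a kept cell set.

    ``remaining_cells`` is a boolean mask or array of flat cell ids; it
    must be a subset of the base (denominator) cells, which default to
    the stack's valid cells.
    """
    table = table or branches.table
    n_cells = branches.grid.n_cells
    base = (
        branches.valid_mask
        if base_cells is None
        else _as_cell_mask(base_cells, n_cells) & branches.valid_mask
    )
    remaining = _as_cell_mask(remaining_cells, n_cells)
    if (remaining & ~base).any():
        raise ValueError("remaining cells are not a subset of the base cells")
    vals, T, keep = _branch_totals(branches, base, on_zero)
    L = np.array([b.length for b in table], dtype=float)[keep]
    if L.sum() <= 0:
        raise ValueError("total PD is zero; retention undefined")
    S = vals[keep][:, remaining].sum(axis=1)
    return float((L * (S / T[keep])).sum() / L.sum())


@dataclass
class PDCurve:
    """PD retained as a function of the fraction of cells removed.

    Points are stored per removal batch; ``value_at`` interpolates
    linearly between stored points (interpolated queries are flagged by
    the return type of :meth:`value_at` being between stored fractions).
    """

    fractions: np.ndarray  # fraction of cells removed, starts at 0
    pd_remaining: np.ndarray  # starts at 1
    denominator: str = "analyzable cells"
    scenario: str = ""

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.pd_remaining = np.asarray(self.pd_remaining, dtype=float)
        if self.fractions[0] != 0 or self.pd_remaining[0] != 1:
            raise ValueError("curve must start at (0, 1)")
        if (np.diff(self.fractions) <= 0).any():
            raise ValueError("fractions must be strictly increasing")
        if (np.diff(self.pd_remaining) > 1e-12).any():
            raise ValueError("PD remaining must be non-increasing")

    def value_at(self, fraction_removed: float) -> float:
        return float(np.interp(fraction_removed, self.fractions, self.pd_remaining))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fraction_removed": self.fractions, "pd_remaining": self.pd_remaining}
        )

    def plot(self, ax=None, **kwargs):
        """Basic PD-loss curve plot (fraction removed vs PD remaining)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        label = kwargs.pop("label", self.scenario or None)
        ax.plot(self.fractions, self.pd_remaining, label=label, **kwargs)
        ax.set_xlabel("fraction of cells removed")
        ax.set_ylabel("proportion of PD remaining")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1.02)
        if label:
            ax.legend()
        return ax


def pd_curve(
    result: PriorityResult,
    branches: BranchStack,
    table: Optional[BranchTable] = None,
    on_zero: str = "error",
    scenario: str = "",
) -> PDCurve:
    """PD-retention curve of a removal run, one point per warp batch.

    Computed by incremental subtraction of each batch's branch
    probabilities from the remaining representation (cheap), which
    agrees with from-scratch recomputation to within accumulation
    tolerance.
    """
    table = table or branches.table
    if not result.grid.same_shape(branches.grid):
        raise ValueError("result and branch stack grids do not match")
    base = np.zeros(branches.grid.n_cells, dtype=bool)
    base[result.removal_order] = True
    base &= branches.valid_mask
    vals, T, keep = _branch_totals(branches, base, on_zero)
    L = np.array([b.length for b in table], dtype=float)[keep]
    total_L = L.sum()
    vals = vals[keep]
    T = T[keep]

    n = result.n_ranked
    S = T.copy()
    fracs = [0.0]
    pd_rem = [1.0]
    pos = 0
    for size in result.batch_sizes:
        batch = result.removal_order[pos : pos + size]
        S -= vals[:, batch].sum(axis=1)
        np.maximum(S, 0.0, out=S)
        pos += size
        fracs.append(pos / n)
        pd_rem.append(float((L * (S / T)).sum() / total_L))
    pd_arr = np.minimum.accumulate(np.array(pd_rem))  # guard float dust
    return PDCurve(np.array(fracs), pd_arr, scenario=scenario)


def protected_pd(
    mask: MaskGrid,
    protected_levels: Union[set, Sequence[int]],
    branches: BranchStack,
    table: Optional[BranchTable] = None,
    base_cells: Optional[np.ndarray] = None,
    on_zero: str = "error",
) -> float:
    """PD retained if only cells of the protected mask levels are kept."""
    protected_levels = set(int(l) for l in protected_levels)
    if not protected_levels <= set(mask.declared_levels):
        raise ValueError(
            f"protected levels {sorted(protected_levels)} not all declared "
            f"({mask.declared_levels})"
        )
    if not mask.grid.same_shape(branches.grid):
        raise ValueError("mask and branch stack grids do not match")
    remaining = np.isin(mask.levels, sorted(protected_levels)) & branches.valid_mask
    if base_cells is None:
        base_cells = branches.valid_mask & mask.analysis_mask
        remaining = remaining & base_cells
    return pd_retention(
        remaining, branches, table, base_cells=base_cells, on_zero=on_zero
    )


@dataclass
class ScenarioReport:
    """Outcome of one reserve-configuration scenario."""

    name: str
    pd_before: float
    pd_after: float
    pd_gain: float
    expansion_cells: np.ndarray
    n_protected: int
    n_expansion: int
    expansion_fraction: float
    fraction_of_landscape: float

    def __str__(self) -> str:
        return (
            f"{self.name}: protected PD {self.pd_before:.4f} → "
            f"{self.pd_after:.4f} (gain {self.pd_gain:.4f}) by adding "
            f"{self.n_expansion} cells ({100 * self.fraction_of_landscape:.2f}% "
            f"of the landscape; {100 * self.expansion_fraction:.0f}% of the "
            f"reserve area)"
        )


def expansion_scenario(
    result: PriorityResult,
    mask: MaskGrid,
    protected_levels: Union[set, Sequence[int]],
    expansion_fraction: float,
    branches: BranchStack,
    table: Optional[BranchTable] = None,
    name: str = "expand reserves",
    on_zero: str = "error",
) -> ScenarioReport:
    """Grow the reserve system by a fraction of its cell count.

    The ranking must come from a run where protected cells were forced
    last (highest mask level); the ⌈fraction · #protected⌉ best-ranked
    unprotected cells are added and the PD gain reported. Expansion is
    counted in cells (equal-area planning units), so a 5% area expansion
    is 5% of the protected cell count.
    """
    if expansion_fraction < 0:
        raise ValueError("expansion_fraction must be >= 0")
    protected_levels = set(int(l) for l in protected_levels)
    table = table or branches.table
    n_cells = branches.grid.n_cells
    ranked = np.zeros(n_cells, dtype=bool)
    ranked[result.removal_order] = True
    protected = np.isin(mask.levels, sorted(protected_levels)) & ranked
    n_protected = int(protected.sum())
    if n_protected == 0:
        raise ValueError("no protected cells under the given levels")
    # precondition: protected areas were forced last in the ranking
    tail = result.removal_order[result.n_ranked - n_protected :]
    if not protected[tail].all():
        raise ValueError(
            "ranking does not have the protected cells forced last; run "
            "prioritize with a mask whose highest level is the reserves"
        )
    n_expand = math.ceil(expansion_fraction * n_protected)
    unprotected_best_first = result.removal_order[::-1]
    unprotected_best_first = unprotected_best_first[
        ~protected[unprotected_best_first]
    ]
    if n_expand > len(unprotected_best_first):
        raise ValueError(
            f"expansion of {n_expand} cells exceeds the "
            f"{len(unprotected_best_first)} available unprotected cells"
        )
    expansion_cells = unprotected_best_first[:n_expand]
    base = ranked & branches.valid_mask
    pd_before = pd_retention(
        protected & base, branches, table, base_cells=base, on_zero=on_zero
    )
    augmented = protected.copy()
    augmented[expansion_cells] = True
    pd_after = pd_retention(
        augmented & base, branches, table, base_cells=base, on_zero=on_zero
    )
    return ScenarioReport(
        name=name,
        pd_before=pd_before,
        pd_after=pd_after,
        pd_gain=pd_after - pd_before,
        expansion_cells=expansion_cells,
        n_protected=n_protected,
        n_expansion=n_expand,
        expansion_fraction=float(expansion_fraction),
        fraction_of_landscape=n_expand / result.n_ranked,
    )


@dataclass
class TenureSummary:
    """Per-branch distribution across tenure categories with risk classes."""

    frame: pd.DataFrame
    protected_levels: tuple
    park_levels: tuple
    thresholds: tuple
    denominator: str = "full modelled distribution (all mapped cells)"

    @property
    def class_counts(self) -> pd.Series:
        return (
            self.frame["vulnerability"]
            .value_counts()
            .reindex(VULNERABILITY_CLASSES, fill_value=0)
        )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def tenure_summary(
    branches: BranchStack,
    table: Optional[BranchTable],
    mask: MaskGrid,
    protected_levels: Union[set, Sequence[int]],
    thresholds: tuple = (0.01, 0.05),
    park_levels: Optional[Union[set, Sequence[int]]] = None,
) -> TenureSummary:
    """How much of each branch's distribution falls in each tenure category.

    The denominator is the branch's full distribution over all mapped
    (valid) cells, including cleared/level-0 territory, so past habitat
    loss counts against a branch. Classes relative to the protected
    category: ``outside_parks`` if the branch has zero representation in
    any park level, ``lt_1pct`` if its protected share is below the
    first threshold, ``1_to_5pct`` below the second, else ``gt_5pct``
    (shares exactly at a threshold go to the less vulnerable class).
    ``park_levels`` (e.g. development + protected zones) defaults to
    ``protected_levels``.
    """
    table = table or branches.table
    protected_levels = tuple(sorted(int(l) for l in protected_levels))
    park_levels = (
        protected_levels
        if park_levels is None
        else tuple(sorted(int(l) for l in park_levels))
    )
    declared = set(mask.declared_levels)
    if not set(protected_levels) <= declared or not set(park_levels) <= declared:
        raise ValueError("protected/park levels must be declared mask levels")
    if not mask.grid.same_shape(branches.grid):
        raise ValueError("mask and branch stack grids do not match")
    t_lo, t_hi = thresholds
    if not 0 < t_lo < t_hi < 1:
        raise ValueError("thresholds must satisfy 0 < lo < hi < 1")

    vals = np.nan_to_num(branches.values, nan=0.0)
    valid = branches.valid_mask
    totals = vals[:, valid].sum(axis=1)
    if (totals <= 0).any():
        zero_ids = [b.branch_id for b, t in zip(branches.table, totals) if t <= 0]
        raise ValueError(f"branch(es) with zero total distribution: {zero_ids}")

    rows = {}
    for level in mask.declared_levels:
        sel = (mask.levels == level) & valid
        rows[f"prop_level_{level}"] = vals[:, sel].sum(axis=1) / totals
    frame = pd.DataFrame(rows)
    frame.insert(0, "branch_id", [b.branch_id for b in branches.table])
    frame.insert(1, "length", [b.length for b in branches.table])
    frame.insert(2, "is_tip", [b.is_tip for b in branches.table])
    prot = sum(frame[f"prop_level_{l}"] for l in protected_levels)
    park = sum(frame[f"prop_level_{l}"] for l in park_levels)
    frame["protected_prop"] = prot
    frame["park_prop"] = park

    def classify(park_p: float, prot_p: float) -> str:
        if park_p == 0:
            return "outside_parks"
        if prot_p < t_lo:
            return "lt_1pct"
        if prot_p < t_hi:
            return "1_to_5pct"
        return "gt_5pct"

    frame["vulnerability"] = [
        classify(pk, pr) for pk, pr in zip(frame["park_prop"], frame["protected_prop"])
    ]
    return TenureSummary(
        frame=frame,
        protected_levels=protected_levels,
        park_levels=park_levels,
        thresholds=(float(t_lo), float(t_hi)),
    )
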