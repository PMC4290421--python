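import numpy as np
import pytest

from phylozone import (
    BranchStack,
    RasterStack,
    GridSpec,
    build_branch_stack,
    enumerate_branches,
    parse_tree,
)


def make_stack(values, ids=None) -> RasterStack:
    """Build a stack from an (n_layers, n_rows, n_cols) array; NaN = NoData."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    n_layers, n_rows, n_cols = arr.shape
    if ids is None:
        ids = [f"sp{k}" for k in range(n_layers)]
    flat = arr.reshape(n_layers, -1)
    valid = ~np.isnan(flat).any(axis=0)
    flat = flat.copy()
    flat[:, ~valid] = np.nan
    return RasterStack(GridSpec(n_rows, n_cols), list(ids), flat, valid)


@pytest.fixture
def toy_tree():
    """((A:1,B:1):1,C:2); — 4 branches, total PD 5."""
    return parse_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def toy_branches(toy_tree):
    return enumerate_branches(toy_tree)


@pytest.fixture
def toy_branch_stack(toy_tree, toy_branches) -> BranchStack:
    rng = np.random.default_rng(7)
    species = make_stack(rng.uniform(0, 0.9, size=(3, 3, 3)), ids=["A", "B", "C"])
    return build_branch_stack(species, toy_branches)
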