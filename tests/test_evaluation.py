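import numpy as np
import pytest

from phylozone import (
    GridSpec,
    PrioritizerConfig,
    build_branch_stack,
    enumerate_branches,
    expansion_scenario,
    parse_tree,
    pd_curve,
    pd_retention,
    prioritize,
    protected_pd,
    tenure_summary,
)
from phylozone.branch_propagation import BranchStack
from phylozone.landscape import MaskGrid, RasterStack
from phylozone.synthetic_data import (
    SimulationConfig,
    simulate_landscape,
    simulate_phylogeny,
)

from conftest import make_stack
from oracles import pd_retention_oracle


def _toy_two_branch_stack():
    """Two cells, two equal-length branches: B = [[0.5, 0.5], [1.0, 0.0]]."""
    tree = parse_tree("(A:1,B:1);")
    table = enumerate_branches(tree)
    ids = table.tip_labels
    vals = {"A": [[0.5, 0.5]], "B": [[1.0, 0.0]]}
    species = make_stack(
        np.array([vals[ids[0]], vals[ids[1]]]), ids=ids
    )
    return build_branch_stack(species, table)


def _random_branch_stack(n_species, n_rows, n_cols, seed):
    tree = simulate_phylogeny(SimulationConfig(n_species=n_species, seed=seed))
    table = enumerate_branches(tree)
    rng = np.random.default_rng(seed + 1000)
    species = make_stack(
        rng.uniform(0.05, 1, (n_species, n_rows, n_cols)), ids=table.tip_labels
    )
    return build_branch_stack(species, table)


class TestPDRetention:
    def test_full_landscape_is_exactly_one(self):
        bstack = _random_branch_stack(5, 4, 4, 1)
        assert pd_retention(bstack.valid_mask, bstack) == 1.0

    def test_empty_set_is_exactly_zero(self):
        bstack = _random_branch_stack(5, 4, 4, 2)
        assert pd_retention(np.array([], dtype=int), bstack) == 0.0

    def test_toy_hand_computation(self):
        # keep cell 0: branch A keeps 0.5/1.0, branch B keeps 1.0/1.0
        bstack = _toy_two_branch_stack()
        assert pd_retention(np.array([0]), bstack) == pytest.approx(0.75, abs=1e-15)
        assert pd_retention(np.array([1]), bstack) == pytest.approx(0.25, abs=1e-15)

    def test_zero_representation_branch_errors_unless_dropped(self):
        tree = parse_tree("(A:1,B:1);")
        table = enumerate_branches(tree)
        species = make_stack(np.array([[[0.5, 0.5]], [[0.0, 0.0]]]), ids=["A", "B"])
        bstack = build_branch_stack(species, table)
        with pytest.raises(ValueError, match="zero total representation"):
            pd_retention(np.array([0]), bstack)
        with pytest.warns(UserWarning, match="dropping"):
            val = pd_retention(np.array([0]), bstack, on_zero="drop")
        assert val == pytest.approx(0.5)

    def test_star_tree_equal_lengths_reduces_to_mean_species_fraction(self):
        tree = parse_tree("(A:1,B:1,C:1);")
        table = enumerate_branches(tree)
        rng = np.random.default_rng(5)
        species = make_stack(rng.uniform(0.1, 1, (3, 3, 3)), ids=table.tip_labels)
        bstack = build_branch_stack(species, table)
        keep = np.array([0, 3, 4, 8])
        fractions = [
            species.values[k, keep].sum() / species.values[k].sum() for k in range(3)
        ]
        assert pd_retention(keep, bstack) == pytest.approx(np.mean(fractions), abs=1e-12)

    def test_matches_direct_oracle(self):
        bstack = _random_branch_stack(6, 5, 5, 3)
        keep = np.random.default_rng(6).choice(25, size=10, replace=False)
        expected = pd_retention_oracle(
            keep.tolist(),
            bstack.values,
            bstack.lengths,
            list(range(25)),
        )
        assert pd_retention(keep, bstack) == pytest.approx(expected, abs=1e-12)


class TestPDCurve:
    def test_uniform_single_branch_is_straight_line(self):
        tree = parse_tree("(A:1,B:1);")
        table = enumerate_branches(tree)
        species = make_stack(np.full((2, 4, 4), 0.5), ids=table.tip_labels)
        bstack = build_branch_stack(species, table)
        res = prioritize(bstack, config=PrioritizerConfig(warp=1))
        curve = pd_curve(res, bstack)
        np.testing.assert_allclose(
            curve.pd_remaining, 1 - curve.fractions, atol=1e-12
        )

    def test_incremental_matches_from_scratch_every_batch(self):
        bstack = _random_branch_stack(6, 15, 15, 7)
        res = prioritize(bstack, config=PrioritizerConfig(warp=7))
        curve = pd_curve(res, bstack)
        pos = 0
        for k, size in enumerate(res.batch_sizes, start=1):
            pos += size
            expected = pd_retention(res.removal_order[pos:], bstack)
            assert curve.pd_remaining[k] == pytest.approx(expected, abs=1e-9)

    def test_curve_monotone_and_endpoints(self):
        bstack = _random_branch_stack(5, 8, 8, 8)
        res = prioritize(bstack, config=PrioritizerConfig(warp=10))
        curve = pd_curve(res, bstack)
        assert curve.fractions[0] == 0 and curve.pd_remaining[0] == 1
        assert curve.fractions[-1] == 1
        assert curve.pd_remaining[-1] == pytest.approx(0.0, abs=1e-9)
        assert (np.diff(curve.pd_remaining) <= 1e-12).all()

    def test_interpolated_query(self):
        bstack = _random_branch_stack(4, 6, 6, 9)
        res = prioritize(bstack, config=PrioritizerConfig(warp=9))
        curve = pd_curve(res, bstack)
        assert curve.value_at(0.0) == 1.0
        mid = curve.value_at(0.5)
        assert 0 < mid < 1

    def test_constrained_run_matching_unconstrained_top_set_gives_same_curve(self):
        bstack = _random_branch_stack(5, 7, 7, 10)
        free = prioritize(bstack, config=PrioritizerConfig(warp=1))
        top = free.top_fraction(0.3)
        levels = np.ones(bstack.grid.n_cells, dtype=int)
        levels[top] = 2
        mask = MaskGrid(bstack.grid, levels, declared_levels=(1, 2))
        forced = prioritize(bstack, mask, PrioritizerConfig(warp=1))
        np.testing.assert_array_equal(free.removal_order, forced.removal_order)
        np.testing.assert_allclose(
            pd_curve(free, bstack).pd_remaining,
            pd_curve(forced, bstack).pd_remaining,
            atol=1e-12,
        )


class TestProtectedPD:
    def test_all_and_none_protected(self):
        bstack = _toy_two_branch_stack()
        levels_all = MaskGrid(bstack.grid, [1, 1], declared_levels=(0, 1))
        levels_none = MaskGrid(bstack.grid, [0, 0], declared_levels=(0, 1))
        assert protected_pd(levels_all, {1}, bstack) == 1.0
        assert protected_pd(levels_none, {1}, bstack) == 0.0

    def test_toy_cell_protected(self):
        bstack = _toy_two_branch_stack()
        mask = MaskGrid(bstack.grid, [1, 0], declared_levels=(0, 1))
        assert protected_pd(mask, {1}, bstack) == pytest.approx(0.75, abs=1e-15)

    def test_undeclared_protected_level_rejected(self):
        bstack = _toy_two_branch_stack()
        mask = MaskGrid(bstack.grid, [1, 0], declared_levels=(0, 1))
        with pytest.raises(ValueError, match="not all declared"):
            protected_pd(mask, {5}, bstack)


class TestExpansionScenario:
    def _setup(self, seed=0, protected_frac=0.1):
        cfg = SimulationConfig(
            n_species=5,
            n_rows=20,
            n_cols=20,
            seed=seed,
            tenure_fractions={1: 1 - protected_frac, 2: protected_frac},
        )
        tree, species, mask = simulate_landscape(cfg)
        bstack = build_branch_stack(species, enumerate_branches(tree))
        res = prioritize(bstack, mask, PrioritizerConfig(warp=1))
        return bstack, mask, res

    def test_zero_fraction_zero_gain(self):
        bstack, mask, res = self._setup()
        rep = expansion_scenario(res, mask, {2}, 0.0, bstack)
        assert rep.n_expansion == 0
        assert rep.pd_gain == 0.0

    def test_exhaustive_expansion_reaches_full_landscape(self):
        bstack, mask, res = self._setup()
        n_prot = (mask.levels == 2).sum()
        n_unprot = (mask.levels == 1).sum()
        rep = expansion_scenario(res, mask, {2}, n_unprot / n_prot, bstack)
        assert rep.pd_after == pytest.approx(1.0, abs=1e-12)

    def test_gain_matches_from_scratch_retention_difference(self):
        """5% expansion of a 10%-protected synthetic landscape."""
        bstack, mask, res = self._setup(seed=3)
        rep = expansion_scenario(res, mask, {2}, 0.05, bstack)
        protected = np.flatnonzero(mask.levels == 2)
        augmented = np.concatenate([protected, rep.expansion_cells])
        before = pd_retention(protected, bstack)
        after = pd_retention(augmented, bstack)
        assert rep.pd_gain == pytest.approx(after - before, abs=1e-9)
        assert rep.pd_gain >= 0

    def test_expansion_beyond_available_cells_rejected(self):
        bstack, mask, res = self._setup()
        with pytest.raises(ValueError, match="exceeds"):
            expansion_scenario(res, mask, {2}, 50.0, bstack)

    def test_ranking_without_reserves_forced_last_rejected(self):
        bstack, mask, res = self._setup()
        free = prioritize(bstack, None, PrioritizerConfig(warp=1))
        with pytest.raises(ValueError, match="forced last"):
            expansion_scenario(free, mask, {2}, 0.05, bstack)


class TestTenureSummary:
    def _stack_with_props(self, protected_props):
        """One 1×n grid per branch proportion: species k has prop in cell 1."""
        tree = parse_tree("(A:1,B:1);")
        table = enumerate_branches(tree)
        pa, pb = protected_props
        species = make_stack(
            np.array([[[1 - pa, pa]], [[1 - pb, pb]]]), ids=table.tip_labels
        )
        bstack = build_branch_stack(species, table)
        mask = MaskGrid(bstack.grid, [1, 2], declared_levels=(1, 2))
        return bstack, mask, table

    def test_wholly_protected_branch(self):
        tree = parse_tree("(A:1,B:1);")
        table = enumerate_branches(tree)
        species = make_stack(np.array([[[0.0, 0.7]], [[0.0, 0.2]]]), ids=table.tip_labels)
        bstack = build_branch_stack(species, table)
        mask = MaskGrid(bstack.grid, [1, 2], declared_levels=(1, 2))
        ts = tenure_summary(bstack, table, mask, {2})
        assert (ts.frame["prop_level_2"] == 1.0).all()
        assert (ts.frame["vulnerability"] == "gt_5pct").all()

    def test_sub_one_percent_is_most_vulnerable_class(self):
        bstack, mask, table = self._stack_with_props((0.004, 0.5))
        ts = tenure_summary(bstack, table, mask, {2})
        by_id = ts.frame.set_index("branch_id")["vulnerability"]
        tip_a = next(b.branch_id for b in table if b.descendant_tips == {"A"})
        assert by_id[tip_a] == "lt_1pct"

    @pytest.mark.parametrize(
        "prop,expected",
        [(0.0099, "lt_1pct"), (0.01, "1_to_5pct"), (0.0499, "1_to_5pct"), (0.05, "gt_5pct")],
    )
    def test_threshold_edges_go_to_less_vulnerable_class(self, prop, expected):
        bstack, mask, table = self._stack_with_props((prop, 0.5))
        ts = tenure_summary(bstack, table, mask, {2})
        by_id = ts.frame.set_index("branch_id")["vulnerability"]
        tip_a = next(b.branch_id for b in table if b.descendant_tips == {"A"})
        assert by_id[tip_a] == expected

    def test_outside_parks_uses_park_levels_not_protected_levels(self):
        tree = parse_tree("((A:1,B:1):1,C:1);")
        table = enumerate_branches(tree)
        # A only on unprotected land (level 1); B and C split across park levels 2/3
        layers = {"A": [[0.8, 0.0, 0.0]], "B": [[0.0, 0.3, 0.1]], "C": [[0.2, 0.2, 0.2]]}
        species = make_stack(
            np.array([layers[t] for t in table.tip_labels]), ids=table.tip_labels
        )
        bstack = build_branch_stack(species, table)
        mask = MaskGrid(bstack.grid, [1, 2, 3], declared_levels=(1, 2, 3))
        ts = tenure_summary(bstack, table, mask, {3}, park_levels={2, 3})
        by_set = {
            frozenset(table[int(i)].descendant_tips): v
            for i, v in zip(ts.frame["branch_id"], ts.frame["vulnerability"])
        }
        assert by_set[frozenset({"A"})] == "outside_parks"
        assert by_set[frozenset({"B"})] == "gt_5pct"  # 0.1/0.4 protected
        assert by_set[frozenset({"A", "B"})] != "outside_parks"

    def test_category_proportions_sum_to_one(self):
        cfg = SimulationConfig(n_species=8, n_rows=12, n_cols=12, seed=6)
        tree, species, mask = simulate_landscape(cfg)
        bstack = build_branch_stack(species, enumerate_branches(tree))
        ts = tenure_summary(bstack, None, mask, {3}, park_levels={2, 3})
        prop_cols = [c for c in ts.frame.columns if c.startswith("prop_level_")]
        np.testing.assert_allclose(ts.frame[prop_cols].sum(axis=1), 1.0, atol=1e-9)

    def test_zero_distribution_branch_rejected(self):
        tree = parse_tree("(A:1,B:1);")
        table = enumerate_branches(tree)
        species = make_stack(np.array([[[0.5, 0.5]], [[0.0, 0.0]]]), ids=table.tip_labels)
        bstack = build_branch_stack(species, table)
        mask = MaskGrid(bstack.grid, [1, 2], declared_levels=(1, 2))
        with pytest.raises(ValueError, match="zero total distribution"):
            tenure_summary(bstack, table, mask, {2})
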