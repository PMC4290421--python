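# phylozone

Phylogenetic diversity (PD) in spatial conservation prioritization.

Conservation planning usually ranks land by how well it represents
species. `phylozone` instead treats **every branch of a phylogeny** as a
conservation feature, so that plans preserve as much of a clade's
evolutionary history as possible — deep lineages and narrow endemics
alike. It is aimed at conservation scientists and analysts who have (a)
a phylogeny for their study group and (b) per-species occurrence
probability rasters (typically species distribution model outputs), and
who want Zonation-style priority rankings, reserve-scenario evaluations,
and per-lineage vulnerability reports in terms of PD.

## The method

**Branch occurrence layers.** Each species is a terminal branch with a
probability-of-occurrence raster `P_n,j` (species *n*, grid cell *j*).
A branch occurs in a cell if *any* of its descendant species does;
assuming independence within a cell, the occurrence probability of
branch *i* is

    B_i,j = 1 − Π_n (1 − P_n,j)

over the branch's descendant species. Tip branches are their species
layers verbatim. Taxa without molecular data can be grafted at the stem
node of their closest relative with branch length 0, which leaves total
PD unchanged.

**Priority ranking.** A greedy complementarity engine starts with the
whole landscape "protected" and iteratively discards the cells whose
loss least damages the remaining representation `S_i = Σ_j∈remaining B_i,j`
of the features. A cell's marginal loss is

    core-area (CAZ):        max_i  w_i · B_i,j / S_i
    additive-benefit (ABF): Σ_i   w_i · B_i,j / S_i

with weights `w_i` defaulting to branch lengths `L_i`. A *warp factor*
(default 100) removes that many cells per iteration; an integer tenure
mask forces categories of cells (cleared land, unprotected vegetation,
reserves, …) to be removed in a fixed level order, so existing reserves
can be forced into — or development zones out of — the top priorities.

**Evaluation.** The proportion of PD remaining on a kept cell set *q*
out of *Q* is

    PD_remaining = [ Σ_i L_i · (Σ_j∈q B_i,j / Σ_j∈Q B_i,j) ] / Σ_i L_i ,

which is 1 for the full landscape (where it reduces to Faith's PD, the
sum of branch lengths) and 0 for the empty set. On top of this the
package computes PD-loss curves per removal step, protected-PD under a
tenure mask, reserve-expansion scenarios, and per-branch summaries of
how much of each lineage's distribution falls in each tenure category
(with vulnerability classes at <1%, 1–5%, >5% protected).

A seeded synthetic-data module (pure-birth trees, Gaussian range
surfaces with phylogenetic signal in range centres, contiguous tenure
masks) generates complete study landscapes for testing and
demonstration.

## Worked example

```python
import phylozone as pz

cfg = pz.SimulationConfig(n_species=15, n_rows=30, n_cols=30, seed=1)
tree, species, tenure = pz.simulate_landscape(cfg)
table = pz.enumerate_branches(tree)
branches = pz.build_branch_stack(species, table)
print(f"{len(table)} branches, total PD = {table.total_pd:.2f}")

tenure.outside_levels = (0,)          # cleared land sits outside the analysis
print(f"PD in reserves (levels 2+3): {pz.protected_pd(tenure, {2, 3}, branches):.3f}")

result = pz.prioritize(branches, tenure, pz.PrioritizerConfig(rule="caz", warp=100))
curve = pz.pd_curve(result, branches)
print(f"PD remaining with best 10% of cells kept: {curve.value_at(0.9):.3f}")

report = pz.expansion_scenario(result, tenure, {2, 3}, 0.05, branches)
print(report)

summary = pz.tenure_summary(branches, table, tenure, {3}, park_levels={2, 3})
print("vulnerability classes:", summary.class_counts.to_dict())
```

prints

```
28 branches, total PD = 11.94
PD in reserves (levels 2+3): 0.323
PD remaining with best 10% of cells kept: 0.129
expand reserves: protected PD 0.3232 → 0.3722 (gain 0.0490) by adding 8 cells (2.22% of the landscape; 5% of the reserve area)
vulnerability classes: {'outside_parks': 0, 'lt_1pct': 4, '1_to_5pct': 2, 'gt_5pct': 22}
```

Reading: the 15-species tree contributes 28 branch features totalling
11.94 units of PD. The existing (synthetic) reserves happen to capture
32.3% of the PD present in the remaining vegetation. Keeping only the
best-ranked 10% of vegetated cells would retain 12.9% of PD, and
growing the reserve system by 5% of its cell count — placed where the
ranking says — lifts protected PD from 32.3% to 37.2%. Four lineages
have less than 1% of their full modelled distribution (cleared land
included) inside fully protected zones.

The same pipeline is available from the shell via the `phylozone`
command (`simulate`, `branch-layers`, `prioritize`, `evaluate-curve`,
`evaluate-protected`, `expand`, `tenure-report`); see `phylozone --help`.

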