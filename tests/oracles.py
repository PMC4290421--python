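"""Independent reference implementations used only to check the package.

These deliberately use naive loops and from-scratch recomputation so
they share no code path with the library.
"""

import numpy as np


def mc_union_frequency(probs, n_draws, rng) -> float:
    """Empirical frequency of 'at least one event occurs' under independence."""
    p = np.asarray(probs, dtype=float)
    hits = (rng.random((n_draws, p.size)) < p).any(axis=1)
    return float(hits.mean())


def union_probability_recursive(tree_node, tip_probs: dict) -> float:
    """P(any descendant occurs) combined child-subtree by child-subtree.

    Independent of the tip-product formula: combines the children's
    union probabilities as 1 − Π_child (1 − U_child).
    """
    if tree_node.is_leaf():
        return tip_probs[tree_node.taxon.label]
    none = 1.0
    for ch in tree_node.child_nodes():
        none *= 1.0 - union_probability_recursive(ch, tip_probs)
    return 1.0 - none


def greedy_removal_oracle(values, weights, levels, warp, rule):
    """From-scratch re-evaluating greedy cell removal.

    values: (n_features, n_cells) with NaN outside the valid set;
    levels: per-cell mask level (None = single level). Every iteration
    recomputes each feature's remaining representation by direct
    summation over the remaining cells, scores the cells of the lowest
    still-populated level, and removes the `warp` lowest (ties to the
    lowest cell index).
    """
    values = np.asarray(values, dtype=float)
    n_cells = values.shape[1]
    valid = ~np.isnan(values).any(axis=0)
    if levels is None:
        levels = np.zeros(n_cells, dtype=int)
    remaining = set(np.flatnonzero(valid).tolist())
    order = []
    while remaining:
        lowest = min(levels[c] for c in remaining)
        candidates = sorted(c for c in remaining if levels[c] == lowest)
        S = {}
        for i in range(values.shape[0]):
            S[i] = sum(values[i, c] for c in sorted(remaining))
        scored = []
        for c in candidates:
            contribs = [
                weights[i] * values[i, c] / S[i]
                for i in range(values.shape[0])
                if S[i] > 0
            ]
            if not contribs:
                loss = 0.0
            elif rule == "core_area":
                loss = max(contribs)
            else:
                loss = sum(contribs)
            scored.append((loss, c))
        scored.sort()
        batch = [c for _, c in scored[:warp]]
        order.extend(batch)
        remaining -= set(batch)
    return np.array(order, dtype=np.int64)


def pd_retention_oracle(remaining_cells, values, lengths, base_cells) -> float:
    """Direct evaluation of length-weighted mean remaining distribution."""
    values = np.asarray(values, dtype=float)
    acc = 0.0
    for i in range(values.shape[0]):
        total = sum(values[i, c] for c in sorted(base_cells))
        kept = sum(values[i, c] for c in sorted(remaining_cells))
        acc += lengths[i] * kept / total
    return acc / sum(lengths)
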