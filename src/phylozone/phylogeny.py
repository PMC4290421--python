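"""Phylogeny handling: parsing, taxon grafting, and branch enumeration.

Every branch of a rooted phylogeny is treated as a conservation feature.
A branch is identified with the edge subtending a node; the root's own
subtending edge is excluded (it has no defined length in standard newick
and would contribute nothing to a length-weighted diversity sum). Under
this convention the sum of branch lengths over the table equals Faith's
phylogenetic diversity (PD) of the full tree.

Taxa without molecular data can be grafted onto the tree at the stem node
of a designated sibling taxon — i.e. the new tip becomes a child of the
sibling's parent node, forming or extending a polytomy — with a branch
length of zero by default, which leaves total PD unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import dendropy
import pandas as pd

__all__ = [
    "GraftInstruction",
    "Branch",
    "BranchTable",
    "parse_tree",
    "read_tree",
    "validate_tree",
    "total_pd",
    "graft_taxa",
    "read_graft_table",
    "enumerate_branches",
]


@dataclass(frozen=True)
class GraftInstruction:
    """Attach ``new_tip_label`` at the stem node of ``sibling_label``.

    The stem node is the parent end of the sibling's subtending branch;
    the new tip becomes an additional child of that node. ``branch_length``
    defaults to zero so the graft conserves total PD.
    """

    new_tip_label: str
    sibling_label: str
    branch_length: float = 0.0

    def __post_init__(self) -> None:
        if not self.new_tip_label:
            raise ValueError("new_tip_label must be non-empty")
        if self.branch_length < 0:
            raise ValueError("graft branch_length must be >= 0")


@dataclass(frozen=True)
class Branch:
    """One conservation feature: a tree edge with its descendant tip set."""

    branch_id: int
    length: float
    descendant_tips: frozenset
    is_tip: bool


class BranchTable:
    """All branches of a tree, in deterministic preorder, root edge excluded.

    Branch ids are assigned by preorder traversal with children visited in
    newick file order, so repeated enumeration of the same tree yields the
    identical id ↔ descendant-set mapping (needed for reproducible joins
    between branches and raster layers).
    """

    def __init__(self, branches: Sequence[Branch]):
        self.branches = list(branches)
        tips = [b for b in self.branches if b.is_tip]
        labels = [next(iter(b.descendant_tips)) for b in tips]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels in branch table")
        self._by_id = {b.branch_id: b for b in self.branches}
        if len(self._by_id) != len(self.branches):
            raise ValueError("duplicate branch ids")

    def __len__(self) -> int:
        return len(self.branches)

    def __iter__(self) -> Iterator[Branch]:
        return iter(self.branches)

    def __getitem__(self, branch_id: int) -> Branch:
        return self._by_id[branch_id]

    @property
    def tip_labels(self) -> list:
        return [next(iter(b.descendant_tips)) for b in self.branches if b.is_tip]

    @property
    def total_pd(self) -> float:
        """Faith's PD of the full tree: the sum of all branch lengths."""
        return float(sum(b.length for b in self.branches))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "branch_id": [b.branch_id for b in self.branches],
                "length": [b.length for b in self.branches],
                "is_tip": [b.is_tip for b in self.branches],
                "descendant_tips": [
                    ";".join(sorted(b.descendant_tips)) for b in self.branches
                ],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BranchTable":
        branches = [
            Branch(
                branch_id=int(r.branch_id),
                length=float(r.length),
                descendant_tips=frozenset(str(r.descendant_tips).split(";")),
                is_tip=bool(r.is_tip),
            )
            for r in df.itertuples()
        ]
        return cls(branches)

    @classmethod
    def from_csv(cls, path) -> "BranchTable":
        return cls.from_frame(pd.read_csv(path))


def _looks_like_nexus(text: str) -> bool:
    return text.lstrip().upper().startswith("#NEXUS")


def parse_tree(newick_text: str) -> dendropy.Tree:
    """Parse a rooted tree from a newick (or NEXUS trees-block) string.

    All non-root edges must carry branch lengths; node labels (e.g.
    bootstrap/posterior supports) are tolerated and ignored. The returned
    tree is validated: >= 2 tips, unique non-empty tip labels, and all
    branch lengths >= 0.
    """
    schema = "nexus" if _looks_like_nexus(newick_text) else "newick"
    try:
        tree = dendropy.Tree.get(
            data=newick_text,
            schema=schema,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed {schema} tree: {exc}") from exc
    tree.is_rooted = True
    validate_tree(tree)
    return tree


def read_tree(path) -> dendropy.Tree:
    with open(path) as fh:
        return parse_tree(fh.read())


def validate_tree(tree: dendropy.Tree) -> None:
    """Check the Phylogeny invariants; raise ValueError on violation."""
    leaves = [nd for nd in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError(f"tree must have >= 2 tips, found {len(leaves)}")
    labels = []
    for leaf in leaves:
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("tree has a tip with an empty label")
        labels.append(leaf.taxon.label)
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue  # root edge excluded from the feature set
        if nd.edge.length is None:
            raise ValueError("missing branch length on a non-root edge")
        if nd.edge.length < 0:
            raise ValueError(f"negative branch length: {nd.edge.length}")


def total_pd(tree: dendropy.Tree) -> float:
    """Sum of branch lengths over all non-root edges (Faith's PD)."""
    return float(
        sum(
            nd.edge.length
            for nd in tree.preorder_node_iter()
            if nd is not tree.seed_node
        )
    )


def graft_taxa(
    tree: dendropy.Tree, instructions: Iterable[GraftInstruction]
) -> dendropy.Tree:
    """Return a new tree with each instruction applied sequentially.

    Each new tip is attached at the stem node shared with its sibling (the
    parent node of the sibling's subtending edge), creating or extending a
    polytomy. The input tree is not modified.
    """
    out = tree.clone(depth=1)
    for instr in instructions:
        existing = {lf.taxon.label for lf in out.leaf_node_iter()}
        if instr.new_tip_label in existing:
            raise ValueError(f"tip label already present: {instr.new_tip_label!r}")
        sibling = None
        for lf in out.leaf_node_iter():
            if lf.taxon.label == instr.sibling_label:
                sibling = lf
                break
        if sibling is None:
            raise ValueError(f"unknown sibling taxon: {instr.sibling_label!r}")
        stem = sibling.parent_node
        if stem is None:
            raise ValueError(
                f"sibling {instr.sibling_label!r} is the root; cannot graft"
            )
        taxon = out.taxon_namespace.require_taxon(label=instr.new_tip_label)
        new_leaf = dendropy.Node(taxon=taxon, edge_length=float(instr.branch_length))
        stem.add_child(new_leaf)
    validate_tree(out)
    return out


def read_graft_table(path) -> list:
    """Read grafting instructions from CSV columns new_tip,sibling,length."""
    df = pd.read_csv(path)
    required = {"new_tip", "sibling"}
    if not required.issubset(df.columns):
        raise ValueError(f"graft table needs columns {sorted(required)}")
    lengths = df["length"] if "length" in df.columns else [0.0] * len(df)
    return [
        GraftInstruction(str(t), str(s), float(l))
        for t, s, l in zip(df["new_tip"], df["sibling"], lengths)
    ]


def enumerate_branches(tree: dendropy.Tree) -> BranchTable:
    """List every branch as a feature with its length and descendant tips.

    Deterministic: ids follow preorder with children in newick file order.
    For a fully bifurcating tree of n tips this yields 2n − 2 branches.
    """
    validate_tree(tree)
    # bottom-up descendant sets, then emit in preorder
    desc: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            desc[nd] = frozenset({nd.taxon.label})
        else:
            acc = frozenset()
            for ch in nd.child_nodes():
                acc |= desc[ch]
            desc[nd] = acc
    branches = []
    bid = 0
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        branches.append(
            Branch(
                branch_id=bid,
                length=float(nd.edge.length),
                descendant_tips=desc[nd],
                is_tip=nd.is_leaf(),
            )
        )
        bid += 1
    return BranchTable(branches)
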