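"""Midpoint rooting and root-to-tip divergence statistics on branch-length trees.

Given an unrooted (or arbitrarily rooted) tree with branch lengths in
substitutions per site, the tree is rooted at the midpoint of the longest
tip-to-tip path — the placement that minimizes the maximum root-to-tip
distance. Root-to-tip distances are then summarized by their median and
interquartile range ("tree height"), and the divergence of a group of tips
is expressed as the percentage its subtree median height represents of the
full-tree median height.

Trees are carried as :class:`dendropy.Tree` objects throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "parse_newick",
    "write_newick",
    "midpoint_root",
    "root_to_tip_distances",
    "HeightSummary",
    "height_summary",
    "extract_subtree",
    "DivergenceFraction",
    "divergence_fraction",
    "group_divergence",
]


def parse_newick(text: str, *, missing_length: str = "error") -> dendropy.Tree:
    """Parse a Newick string into a tree, validating labels and lengths.

    ``missing_length`` controls branches without a stated length: "error"
    rejects them, "zero" sets them to 0. The root branch is exempt. Duplicate
    tip labels are rejected.
    """
    if missing_length not in ("error", "zero"):
        raise ValueError(f"unknown missing_length policy {missing_length!r}")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        raise ValueError(f"invalid Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            if missing_length == "error":
                raise ValueError("branch without a length (use missing_length='zero')")
            node.edge.length = 0.0
        elif node.edge.length < 0:
            raise ValueError("negative branch length")
    return tree


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Serialize a tree to Newick, with lengths at full double precision.

    Returns the string; additionally writes it to ``path`` when given. The
    round trip through :func:`parse_newick` preserves topology, labels, and
    branch lengths to better than 1e-9.
    """
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".17g",
    )
    text = text.strip() + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def root_to_tip_distances(tree: dendropy.Tree) -> dict[str, float]:
    """Path length from the root to every tip, keyed by tip label."""
    out: dict[str, float] = {}
    for leaf in tree.leaf_node_iter():
        out[leaf.taxon.label] = leaf.distance_from_root()
    return out


def _tip_path(tree: dendropy.Tree, u: dendropy.Node, v: dendropy.Node):
    """Node path u ... v through their MRCA."""
    up = []
    node = u
    while node is not None:
        up.append(node)
        node = node.parent_node
    anc = set(id(n) for n in up)
    down = []
    node = v
    while id(node) not in anc:
        down.append(node)
        node = node.parent_node
    mrca = node
    path = up[: up.index(mrca) + 1] + list(reversed(down))
    return path


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root the tree at the midpoint of the longest tip-to-tip path.

    Ties between equally long paths are broken by the lexicographically
    smallest tip-label pair, making the result deterministic. When the
    midpoint falls exactly on a node (possible with zero-length branches),
    the tree is rooted at that node. A tree whose branch lengths are all
    zero is returned rooted as-is, with a warning. The input is not
    modified.
    """
    tree = tree.clone(depth=1)
    leaves = sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    if len(leaves) < 2:
        return tree
    # depth of every node from the current seed, to get patristic distances
    depth = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)

    best = None  # (distance, label_a, label_b, leaf_a, leaf_b)
    for i, a in enumerate(leaves):
        for b in leaves[i + 1 :]:
            path = _tip_path(tree, a, b)
            mrca = min(path, key=lambda n: depth[id(n)])
            d = depth[id(a)] + depth[id(b)] - 2 * depth[id(mrca)]
            key = (-d, a.taxon.label, b.taxon.label)
            if best is None or key < best[0]:
                best = (key, a, b, d)
    _, a, b, diameter = best
    if diameter <= 0.0:
        warnings.warn("all tip-to-tip distances are zero; rooting left unchanged")
        return tree

    path = _tip_path(tree, a, b)
    # cumulative distance from a along the path
    cum = [0.0]
    for prev, node in zip(path, path[1:]):
        if node.parent_node is prev:
            L = node.edge.length or 0.0
        else:
            L = prev.edge.length or 0.0
        cum.append(cum[-1] + L)
    half = diameter / 2.0
    eps = 1e-12 * max(1.0, diameter)
    for i, node in enumerate(path):
        if abs(cum[i] - half) <= eps:
            if node is not tree.seed_node:
                tree.reroot_at_node(node, suppress_unifurcations=True)
            tree.seed_node.edge.length = None
            return tree
    i = next(i for i in range(len(path) - 1) if cum[i] < half < cum[i + 1])
    n_i, n_j = path[i], path[i + 1]
    if n_j.parent_node is n_i:  # walking down: n_j is the edge's head
        edge = n_j.edge
        head_dist = cum[i + 1] - half
    else:  # walking up: n_i is the head
        edge = n_i.edge
        head_dist = half - cum[i]
    tree.reroot_at_edge(
        edge,
        length1=edge.length - head_dist,
        length2=head_dist,
        suppress_unifurcations=True,
    )
    tree.seed_node.edge.length = None
    return tree


@dataclass(frozen=True)
class HeightSummary:
    """Median and interquartile range of root-to-tip distances."""

    median: float
    q1: float
    q3: float
    n_tips: int

    def __str__(self) -> str:  # e.g. "2.82 [2.27-4.28]"
        return f"{self.median:g} [{self.q1:g}-{self.q3:g}] (n={self.n_tips})"


def height_summary(tree: dendropy.Tree) -> HeightSummary:
    """Summarize root-to-tip path lengths of a rooted tree.

    Quartiles use linear interpolation between order statistics (the
    inclusive method), fixed for reproducibility.
    """
    dists = np.array(sorted(root_to_tip_distances(tree).values()))
    if dists.size == 0:
        raise ValueError("tree has no tips")
    q1, med, q3 = np.percentile(dists, [25, 50, 75], method="linear")
    return HeightSummary(median=float(med), q1=float(q1), q3=float(q3),
                         n_tips=int(dists.size))


def extract_subtree(tree: dendropy.Tree, tips: set[str]) -> dendropy.Tree:
    """Minimal path-preserving subtree over ``tips``, rooted at their MRCA.

    Branch lengths along retained paths are preserved (collapsed
    unifurcations sum their lengths). Unknown labels are an error.
    """
    if not tips:
        raise ValueError("tip set must be non-empty")
    have = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown = set(tips) - have
    if unknown:
        raise ValueError(f"unknown tip labels: {sorted(unknown)}")
    sub = tree.extract_tree_with_taxa_labels(labels=set(tips))
    # walk the root down to the MRCA of the retained tips
    while len(sub.seed_node.child_nodes()) == 1:
        child = sub.seed_node.child_nodes()[0]
        sub.seed_node.remove_child(child)
        sub.seed_node = child
    sub.seed_node.edge.length = None
    sub.seed_node.parent_node = None
    return sub


@dataclass(frozen=True)
class DivergenceFraction:
    """A group's subtree median height as a percentage of the full tree's."""

    group: str
    subtree: HeightSummary
    full: HeightSummary
    percent: int


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def divergence_fraction(
    subtree_summary: HeightSummary,
    full_summary: HeightSummary,
    group: str = "",
) -> DivergenceFraction:
    """Percentage of the full-tree median height a subtree's median reaches.

    Rounded half-up to the nearest integer percent.
    """
    if full_summary.median <= 0:
        raise ValueError("full-tree median height must be positive")
    pct = _round_half_up(100.0 * subtree_summary.median / full_summary.median)
    return DivergenceFraction(
        group=group, subtree=subtree_summary, full=full_summary, percent=pct
    )


def group_divergence(
    tree: dendropy.Tree,
    groups: dict[str, set[str]],
    *,
    reroot_subtree: bool = False,
) -> dict[str, DivergenceFraction]:
    """Midpoint-root a tree and report each group's divergence fraction.

    Each group's subtree is measured from the MRCA within the midpoint-rooted
    full tree; ``reroot_subtree=True`` instead re-roots every extracted
    subtree at its own midpoint before summarizing.
    """
    rooted = midpoint_root(tree)
    full = height_summary(rooted)
    out: dict[str, DivergenceFraction] = {}
    for name, tips in groups.items():
        sub = extract_subtree(rooted, tips)
        if reroot_subtree and len(tips) > 1:
            sub = midpoint_root(sub)
        out[name] = divergence_fraction(height_summary(sub), full, group=name)
    return out
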