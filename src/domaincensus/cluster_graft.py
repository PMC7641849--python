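"""Schematic-tree pipeline: greedy clustering, profiles, UPGMA, and grafting.

A large protein family is summarized as a two-level tree. Sequences are
first clustered greedily at a fraction-identity threshold; each cluster is
aligned (center-star, against its representative) and condensed into a
residue-frequency profile. Clusters whose profile-to-profile similarity is
high relative to their self-scores are merged over a fixed number of
iterations. A UPGMA dendrogram over the final cluster profiles forms the
backbone, and a midpoint-rooted member tree (neighbor joining on alignment
p-distances) is grafted onto each backbone tip, yielding a composite tree
whose tips are the original sequences.

External heavy tools this pipeline mirrors in structure (fast clustering,
profile aligners, ML tree builders) are replaced by the declared simplified
algorithms; each step is pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio import Align, SeqIO

from . import tree_metrics

__all__ = [
    "AMINO_ACIDS",
    "SeqRecord",
    "read_fasta",
    "write_fasta",
    "ClusterParams",
    "SeqCluster",
    "pairwise_identity",
    "greedy_cluster",
    "align_cluster",
    "profile_similarity",
    "self_score",
    "upgma",
    "merge_iterate",
    "build_cluster_tree",
    "GraftedTree",
    "graft",
    "select_representatives",
    "schematic_tree",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP = "-"


@dataclass(frozen=True)
class SeqRecord:
    """A protein sequence: unique id plus residues (20 amino acids + X)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"sequence {self.id!r}: invalid residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path) -> list[SeqRecord]:
    records = [
        SeqRecord(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(path, "fasta")
    ]
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in FASTA")
    return records


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.residues}\n")


@dataclass(frozen=True)
class ClusterParams:
    """Thresholds of the schematic-tree pipeline.

    cluster_threshold : fraction identity for greedy clustering (0.5)
    merge_ratio : profile score to self-score ratio above which clusters
        are merged (0.1)
    iterations : number of merge/realign rounds (5)
    census_threshold : fraction identity for representative selection (0.85)
    """

    cluster_threshold: float = 0.5
    merge_ratio: float = 0.1
    iterations: int = 5
    census_threshold: float = 0.85

    def __post_init__(self) -> None:
        for name in ("cluster_threshold", "merge_ratio", "census_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def _aligner() -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=0,
        open_gap_score=-1,
        extend_gap_score=-1,
    )


def pairwise_identity(a: SeqRecord, b: SeqRecord) -> float:
    """Global-alignment fraction identity between two sequences.

    Alignment scoring: match 1, mismatch 0, linear gap penalty -1; identity
    is the number of identical aligned positions divided by the alignment
    length (columns, gaps included). Symmetric in its arguments.
    """
    if a.residues == b.residues:
        return 1.0
    # fix argument order so the (possibly degenerate) optimum is symmetric
    if (len(b), b.residues) < (len(a), a.residues):
        a, b = b, a
    aln = _aligner().align(a.residues, b.residues)[0]
    return aln.counts().identities / aln.length


def _align_pair(ref: str, other: str) -> tuple[str, str]:
    """Gapped strings of the optimal global alignment (ref first)."""
    aln = _aligner().align(ref, other)[0]
    return str(aln[0]), str(aln[1])


@dataclass
class SeqCluster:
    """A cluster of sequences with an alignment-derived frequency profile.

    ``rows`` holds the center-star multiple alignment (one gapped string per
    member, same order as ``members``); ``profile`` is the per-column
    residue frequency matrix (columns x 21), each column summing to 1.
    """

    members: list[SeqRecord]
    representative: SeqRecord
    rows: list[str] = field(default_factory=list)
    profile: np.ndarray | None = None

    @property
    def member_ids(self) -> list[str]:
        return [m.id for m in self.members]


def _rep_order_key(seq: SeqRecord) -> tuple[int, str]:
    return (-len(seq), seq.id)


def greedy_cluster(
    seqs: Sequence[SeqRecord], threshold: float
) -> list[SeqCluster]:
    """Incremental greedy clustering at a fraction-identity threshold.

    Sequences are processed longest-first (ties by id); each is assigned to
    the first existing cluster whose representative it matches at identity
    >= threshold, otherwise it founds a new cluster with itself as
    representative.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    clusters: list[SeqCluster] = []
    for seq in sorted(seqs, key=_rep_order_key):
        for cl in clusters:
            if pairwise_identity(seq, cl.representative) >= threshold:
                cl.members.append(seq)
                break
        else:
            clusters.append(SeqCluster(members=[seq], representative=seq))
    return clusters


def _merge_center_star(
    master: str, member_rows: list[str], rep_aln: str, mem_aln: str
) -> tuple[str, list[str], str]:
    """Fold one (representative, member) pairwise alignment into the MSA.

    ``master`` is the representative row of the current MSA. Columns where
    the pairwise alignment inserts into the representative become new
    all-gap columns in the existing rows ("once a gap, always a gap").
    Returns the updated master, updated existing rows, and the new member
    row.
    """
    out_master: list[str] = []
    out_member: list[str] = []
    keep_cols: list[int] = []  # index into old MSA columns, -1 for new column
    i = j = 0
    while i < len(master) or j < len(rep_aln):
        if i < len(master) and master[i] == GAP:
            # insert column from an earlier member: new member gets a gap
            out_master.append(GAP)
            out_member.append(GAP)
            keep_cols.append(i)
            i += 1
        elif j < len(rep_aln) and rep_aln[j] == GAP:
            # insertion in the new member: new all-gap column for the others
            out_master.append(GAP)
            out_member.append(mem_aln[j])
            keep_cols.append(-1)
            j += 1
        else:
            out_master.append(master[i])
            out_member.append(mem_aln[j])
            keep_cols.append(i)
            i += 1
            j += 1
    new_rows = [
        "".join(row[c] if c >= 0 else GAP for c in keep_cols) for row in member_rows
    ]
    return "".join(out_master), new_rows, "".join(out_member)


def align_cluster(cluster: SeqCluster) -> SeqCluster:
    """Center-star multiple alignment of a cluster against its representative.

    Each member is globally aligned to the representative and the pairwise
    alignments are merged column-wise; the profile is the per-column residue
    frequency over non-gap characters.
    """
    rep = cluster.representative
    master = rep.residues
    rows: list[str] = []
    order: list[int] = []
    for k, mem in enumerate(cluster.members):
        if mem.id == rep.id:
            continue
        rep_aln, mem_aln = _align_pair(rep.residues, mem.residues)
        master, rows, new_row = _merge_center_star(master, rows, rep_aln, mem_aln)
        rows.append(new_row)
        order.append(k)
    # reassemble rows in member order, representative included
    full_rows: list[str] = [""] * len(cluster.members)
    rep_idx = next(k for k, m in enumerate(cluster.members) if m.id == rep.id)
    full_rows[rep_idx] = master
    for row, k in zip(rows, order):
        full_rows[k] = row
    cluster.rows = full_rows
    cluster.profile = _profile_from_rows(full_rows)
    return cluster


def _profile_from_rows(rows: list[str]) -> np.ndarray:
    length = len(rows[0])
    counts = np.zeros((length, len(AMINO_ACIDS)))
    for row in rows:
        for c, ch in enumerate(row):
            if ch != GAP:
                counts[c, _AA_INDEX[ch]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0  # all-gap columns (cannot arise from center-star)
    return counts / totals


# Expected column dot product of two unrelated profiles under a uniform
# residue background; subtracted so chance similarity scores near zero,
# the way log-odds profile scores behave.
_BACKGROUND = 1.0 / 20.0


def self_score(profile: np.ndarray) -> float:
    """Zero-offset similarity of a profile with itself.

    Mean over columns of the squared frequency-vector norm, background-
    corrected; strictly positive for any non-uniform profile.
    """
    return float(np.mean(np.sum(profile * profile, axis=1) - _BACKGROUND))


def profile_similarity(pa: np.ndarray, pb: np.ndarray) -> float:
    """Best ungapped-offset profile similarity.

    At each offset, columns in the overlap contribute the dot product of
    their frequency vectors minus the uniform-background expectation; the
    sum is normalized by the overlap length and the maximum over offsets is
    returned (floored at 0). Offsets are restricted to overlaps of at least
    half the shorter profile, so a few coincidental columns cannot
    dominate. Symmetric.
    """
    la, lb = len(pa), len(pb)
    if la == 0 or lb == 0:
        raise ValueError("profiles must be non-empty")
    min_overlap = max(1, (min(la, lb) + 1) // 2)
    best = 0.0
    for off in range(-(lb - min_overlap), la - min_overlap + 1):
        a0, b0 = max(0, off), max(0, -off)
        ov = min(la - a0, lb - b0)
        if ov < min_overlap:
            continue
        dot = float(np.einsum("ij,ij->", pa[a0 : a0 + ov], pb[b0 : b0 + ov]))
        score = (dot - ov * _BACKGROUND) / ov
        if score > best:
            best = score
    return best


def upgma(dissimilarity: np.ndarray, labels: Sequence[str]) -> dendropy.Tree:
    """UPGMA dendrogram from a symmetric dissimilarity matrix.

    Node heights equal half the merge dissimilarity, so the result is
    ultrametric; merge ties are resolved deterministically with labels
    pre-sorted lexicographically.
    """
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    d = np.asarray(dissimilarity, dtype=float)
    if np.isnan(d).any():
        raise ValueError("dissimilarity matrix contains NaN")
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    if len(labels) != d.shape[0]:
        raise ValueError("labels do not match matrix size")
    order = np.argsort(np.asarray(labels, dtype=object))
    labels = [labels[i] for i in order]
    d = d[np.ix_(order, order)]
    taxa = dendropy.TaxonNamespace(labels)
    if len(labels) == 1:
        tree = dendropy.Tree(taxon_namespace=taxa)
        tree.seed_node.taxon = taxa[0]
        return tree
    z = linkage(squareform(d, checks=False), method="average")
    nodes: list[dendropy.Node] = []
    heights: list[float] = []
    for label in labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(label)
        nodes.append(node)
        heights.append(0.0)
    for a, b, dist, _ in z:
        parent = dendropy.Node()
        h = dist / 2.0
        for child_idx in (int(a), int(b)):
            child = nodes[child_idx]
            child.edge.length = h - heights[child_idx]
            parent.add_child(child)
        nodes.append(parent)
        heights.append(h)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=nodes[-1])
    tree.is_rooted = True
    return tree


def _similarity_matrix(clusters: Sequence[SeqCluster]) -> np.ndarray:
    n = len(clusters)
    s = np.zeros((n, n))
    for i in range(n):
        s[i, i] = self_score(clusters[i].profile)
        for j in range(i + 1, n):
            s[i, j] = s[j, i] = profile_similarity(
                clusters[i].profile, clusters[j].profile
            )
    return s


def merge_iterate(
    clusters: list[SeqCluster], params: ClusterParams
) -> list[SeqCluster]:
    """Merge clusters whose profile similarity ratio exceeds the threshold.

    Each round computes all pairwise profile similarities, forms the ratio
    score / min(self_a, self_b), and merges — transitively, via union-find —
    every pair with ratio > merge_ratio; merged clusters are realigned
    before the next round. Runs ``params.iterations`` rounds, stopping early
    once no pair qualifies. The number of clusters never increases.
    """
    clusters = [cl if cl.profile is not None else align_cluster(cl) for cl in clusters]
    for _ in range(params.iterations):
        n = len(clusters)
        if n < 2:
            break
        s = _similarity_matrix(clusters)
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        merged_any = False
        for i in range(n):
            for j in range(i + 1, n):
                ratio = s[i, j] / min(s[i, i], s[j, j])
                if ratio > params.merge_ratio:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[max(ri, rj)] = min(ri, rj)
                        merged_any = True
        if not merged_any:
            break
        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)
        new_clusters: list[SeqCluster] = []
        for root in sorted(groups):
            idxs = groups[root]
            if len(idxs) == 1:
                new_clusters.append(clusters[idxs[0]])
                continue
            members = [m for k in idxs for m in clusters[k].members]
            members.sort(key=_rep_order_key)
            merged = SeqCluster(members=members, representative=members[0])
            new_clusters.append(align_cluster(merged))
        clusters = new_clusters
    return clusters


def _p_distance(row_a: str, row_b: str) -> float:
    """Fraction of differing residues over columns where both are aligned."""
    pairs = [
        (x, y) for x, y in zip(row_a, row_b) if x != GAP and y != GAP
    ]
    if not pairs:
        return 1.0
    return sum(1 for x, y in pairs if x != y) / len(pairs)


def build_cluster_tree(cluster: SeqCluster) -> dendropy.Tree:
    """Midpoint-rooted member tree from the cluster alignment.

    Pairwise p-distances on the center-star alignment feed neighbor
    joining; negative NJ branch lengths are clamped to zero and the tree is
    midpoint-rooted. Singletons yield a one-tip tree; pairs a cherry with
    p/2 on each side.
    """
    if cluster.profile is None:
        align_cluster(cluster)
    ids = sorted(cluster.member_ids)
    row_by_id = dict(zip(cluster.member_ids, cluster.rows))
    taxa = dendropy.TaxonNamespace(ids)
    if len(ids) == 1:
        tree = dendropy.Tree(taxon_namespace=taxa)
        tree.seed_node.taxon = taxa[0]
        return tree
    if len(ids) == 2:
        p = _p_distance(row_by_id[ids[0]], row_by_id[ids[1]])
        tree = dendropy.Tree(taxon_namespace=taxa)
        for label in ids:
            child = dendropy.Node()
            child.taxon = taxa.get_taxon(label)
            child.edge.length = p / 2.0
            tree.seed_node.add_child(child)
        tree.is_rooted = True
        return tree
    from skbio import DistanceMatrix
    from skbio.tree import nj

    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _p_distance(row_by_id[ids[i]], row_by_id[ids[j]])
    newick = str(nj(DistanceMatrix(d, ids=ids)))
    tree = tree_metrics.parse_newick(newick, missing_length="zero")
    for node in tree.preorder_node_iter():
        if node.edge.length is not None and node.edge.length < 0:
            node.edge.length = 0.0
    return tree_metrics.midpoint_root(tree)


@dataclass
class GraftedTree:
    """UPGMA backbone over clusters plus grafted per-cluster member trees."""

    backbone: dendropy.Tree
    subtrees: dict[str, dendropy.Tree]
    composite: dendropy.Tree


def graft(
    backbone: dendropy.Tree, cluster_trees: dict[str, dendropy.Tree]
) -> GraftedTree:
    """Attach each cluster's member tree at its backbone tip.

    Backbone tips must correspond one-to-one with the keys of
    ``cluster_trees``. The composite tree keeps every backbone branch
    length; a multi-member subtree replaces its tip in place, a single-tip
    subtree simply relabels the tip with the member id.
    """
    backbone_tips = {leaf.taxon.label for leaf in backbone.leaf_node_iter()}
    if backbone_tips != set(cluster_trees):
        raise ValueError("backbone tips and cluster trees do not correspond")
    composite = backbone.clone(depth=1)
    taxa = dendropy.TaxonNamespace()
    for leaf in list(composite.leaf_node_iter()):
        label = leaf.taxon.label
        sub = cluster_trees[label].clone(depth=1)
        leaf.taxon = None
        sub_leaves = list(sub.leaf_node_iter())
        if len(sub_leaves) == 1:
            leaf.taxon = taxa.new_taxon(sub_leaves[0].taxon.label)
        else:
            for sl in sub_leaves:
                sl.taxon = taxa.new_taxon(sl.taxon.label)
            for child in sub.seed_node.child_nodes():
                leaf.add_child(child)
    composite.taxon_namespace = taxa
    composite.is_rooted = True
    return GraftedTree(
        backbone=backbone, subtrees=dict(cluster_trees), composite=composite
    )


def select_representatives(
    seqs: Sequence[SeqRecord], threshold: float = 0.85
) -> list[SeqRecord]:
    """One representative per greedy cluster at the census identity
    threshold — the de-redundancy step preceding the schematic tree."""
    return [cl.representative for cl in greedy_cluster(seqs, threshold)]


def schematic_tree(
    seqs: Sequence[SeqRecord], params: ClusterParams | None = None
) -> GraftedTree:
    """Full pipeline: cluster, align, merge, UPGMA backbone, graft.

    The backbone dissimilarity is ``1 - s / max(s)`` over the cluster
    similarity matrix (self-scores included in the maximum), a monotone,
    bounded, parameter-free conversion.
    """
    params = params or ClusterParams()
    clusters = greedy_cluster(seqs, params.cluster_threshold)
    for cl in clusters:
        align_cluster(cl)
    clusters = merge_iterate(clusters, params)
    labels = [cl.representative.id for cl in clusters]
    if len(clusters) == 1:
        backbone = upgma(np.zeros((1, 1)), labels)
    else:
        s = _similarity_matrix(clusters)
        d = 1.0 - s / s.max()
        np.fill_diagonal(d, 0.0)
        backbone = upgma(d, labels)
    trees = {
        cl.representative.id: build_cluster_tree(cl) for cl in clusters
    }
    return graft(backbone, trees)
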