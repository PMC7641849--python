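"""Seeded generators for gene tables, two-rate trees, and sequence families.

Each generator emulates the statistical structure one analysis stage
assumes, at desk scale: multi-genus genome collections with operonic domain
associations planted over background noise (for the neighborhood/association
stages), two-clade trees whose clades diverge at controllable fractions of
the full tree height (for the divergence statistics), and sequence families
with controllable within- and between-family divergence (for the
cluster/graft pipeline). Every generator is a pure function of its spec,
whose ``seed`` fixes all randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .genome_io import GeneRecord
from .cluster_graft import SeqRecord

__all__ = [
    "OperonTemplate",
    "GenomeSimSpec",
    "simulate_genomes",
    "TreeSimSpec",
    "simulate_two_rate_tree",
    "tree_groups",
    "SeqSimSpec",
    "simulate_sequence_families",
]

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class OperonTemplate:
    """A block of domains planted contiguously at the anchor gene.

    ``domains`` is laid down on consecutive genes starting at the anchor
    (the anchor's own domain first); ``probability`` is the per-genome
    insertion probability; ``max_jitter`` background genes (0 to the stated
    maximum, uniform) may separate consecutive members.
    """

    domains: tuple[str, ...]
    probability: float = 1.0
    max_jitter: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.probability <= 1:
            raise ValueError("insertion probability must be in [0, 1]")
        if self.max_jitter < 0:
            raise ValueError("max_jitter must be >= 0")

    def adjacent_pairs(self) -> list[tuple[str, str]]:
        """Canonically ordered consecutive domain pairs of the template."""
        return [
            tuple(sorted((a, b)))
            for a, b in zip(self.domains, self.domains[1:])
        ]


@dataclass(frozen=True)
class GenomeSimSpec:
    """Conditions for the simulated genome collection.

    Defaults model a collection the size a single well-sampled bacterial
    class contributes — 10 genera of 10 genomes, one 60-gene contig each —
    with a 4-domain operon (anchor plus three partners, mirroring the
    EVE–TsaD–GpsA–YciI arrangement) planted in 90% of genomes, over a
    background of 25 domain types attached to 90% of genes.
    """

    n_genera: int = 10
    genomes_per_genus: int = 10
    genes_per_contig: int = 60
    anchor_domain: str = "EVE"
    operon_templates: tuple[OperonTemplate, ...] = (
        OperonTemplate(("EVE", "TsaD", "GpsA", "YciI"), probability=0.9),
    )
    background_pool: tuple[str, ...] = tuple(f"bg{i:02d}" for i in range(25))
    background_probability: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.background_probability <= 1:
            raise ValueError("background probability must be in [0, 1]")
        if self.anchor_domain in self.background_pool:
            raise ValueError("anchor domain must not be in the background pool")


def simulate_genomes(spec: GenomeSimSpec) -> list[GeneRecord]:
    """Gene table with planted operons around one anchor gene per genome.

    Each genome is a single contig. Genes receive one background domain
    i.i.d. with the background probability; one gene carries the anchor
    domain, and each template is, with its insertion probability, laid down
    on the genes following the anchor (template members separated by 0 to
    ``max_jitter`` background genes). Template domains overwrite background
    ones.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[GeneRecord] = []
    # room to lay every template right of the anchor even at maximal jitter
    tail = sum(
        (len(t.domains) - 1) * (1 + t.max_jitter) for t in spec.operon_templates
    )
    if spec.genes_per_contig < tail + 1:
        raise ValueError("contig too short for the operon templates")
    for gi in range(spec.n_genera):
        genus = f"genus{gi:02d}"
        for mi in range(spec.genomes_per_genus):
            genome_id = f"{genus}_gen{mi:02d}"
            n = spec.genes_per_contig
            domains: list[tuple[str, ...]] = []
            for _ in range(n):
                if rng.random() < spec.background_probability:
                    domains.append((str(rng.choice(spec.background_pool)),))
                else:
                    domains.append(())
            anchor_pos = int(rng.integers(0, n - tail))
            domains[anchor_pos] = (spec.anchor_domain,)
            cursor = anchor_pos
            for template in spec.operon_templates:
                partners = [d for d in template.domains if d != spec.anchor_domain]
                if rng.random() >= template.probability:
                    continue
                for dom in partners:
                    cursor += 1 + int(rng.integers(0, template.max_jitter + 1))
                    domains[cursor] = (dom,)
            for k in range(n):
                records.append(
                    GeneRecord(
                        genome_id=genome_id,
                        genus=genus,
                        contig_id=f"{genome_id}_c1",
                        gene_id=f"{genome_id}_g{k:04d}",
                        start=k * 1000 + 1,
                        end=k * 1000 + 900,
                        strand="+" if rng.random() < 0.5 else "-",
                        domains=domains[k],
                    )
                )
    return records


@dataclass(frozen=True)
class TreeSimSpec:
    """Two-clade tree with controllable within-clade divergence fractions.

    Tips of clade ``k`` sit at depth ``r_k * full_height`` below their clade
    ancestor, perturbed multiplicatively by ``noise`` (lognormal-free,
    Gaussian on the scale factor); the stem from the root to each clade
    ancestor makes the total root-to-tip depth ``full_height``. With zero
    noise, the recovered divergence fractions are exactly round(100*r_k).
    The default full height matches the scale of a deep protein-domain tree
    (median root-to-tip 2.82 substitutions/site).
    """

    n_tips: int = 20
    r1: float = 0.35
    r2: float = 0.32
    full_height: float = 2.82
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.r1, self.r2):
            if not 0 < r <= 1:
                raise ValueError("height scalers must be in (0, 1]")
        if self.n_tips < 2:
            raise ValueError("each clade needs at least 2 tips")


def _random_clade(
    rng: np.random.Generator,
    labels: list[str],
    top_depth: float,
    tip_depths: dict[str, float],
) -> dendropy.Node:
    """Random bifurcating subtree over ``labels`` whose root sits at
    ``top_depth``; tip edge lengths land each tip at its target depth."""
    node = dendropy.Node()
    if len(labels) == 1:
        node.label = labels[0]
        return node
    k = int(rng.integers(1, len(labels)))
    for part in (labels[:k], labels[k:]):
        floor = min(tip_depths[l] for l in part)
        child_depth = top_depth + float(rng.uniform(0.2, 0.8)) * max(
            0.0, floor - top_depth
        )
        child = _random_clade(rng, part, child_depth, tip_depths)
        if len(part) == 1:
            child.edge.length = max(0.0, tip_depths[part[0]] - top_depth)
        else:
            child.edge.length = child_depth - top_depth
        node.add_child(child)
    return node


def simulate_two_rate_tree(spec: TreeSimSpec) -> dendropy.Tree:
    """Newick-ready two-clade tree realizing the requested height fractions.

    Tip labels are ``cladeA_tNN`` / ``cladeB_tNN``; use :func:`tree_groups`
    to recover the clade partition.
    """
    rng = np.random.default_rng(spec.seed)
    h = spec.full_height
    root = dendropy.Node()
    for clade, r in (("cladeA", spec.r1), ("cladeB", spec.r2)):
        labels = [f"{clade}_t{i:02d}" for i in range(spec.n_tips)]
        depth_mrca = (1.0 - r) * h
        tip_depths = {}
        for l in labels:
            scale = 1.0 + spec.noise * float(rng.standard_normal())
            tip_depths[l] = depth_mrca + max(0.05, scale) * r * h
        mrca = _random_clade(rng, labels, depth_mrca, tip_depths)
        mrca.edge.length = depth_mrca
        root.add_child(mrca)
    tree = dendropy.Tree(seed_node=root)
    tree.is_rooted = True
    # promote leaf labels to taxa
    taxa = tree.taxon_namespace
    for leaf in tree.leaf_node_iter():
        leaf.taxon = taxa.new_taxon(leaf.label)
        leaf.label = None
    return tree


def tree_groups(tree: dendropy.Tree) -> dict[str, set[str]]:
    """Clade partition encoded in the simulated tip labels."""
    groups: dict[str, set[str]] = {}
    for leaf in tree.leaf_node_iter():
        groups.setdefault(leaf.taxon.label.split("_")[0], set()).add(
            leaf.taxon.label
        )
    return groups


@dataclass(frozen=True)
class SeqSimSpec:
    """Sequence families mutated i.i.d. per site from family root sequences.

    Family roots derive from a common ancestor mutated at the
    between-family rate (1.0 = unrelated roots); members derive from their
    family root at the within-family rate. A substitution always changes
    the residue, so the rates are expected p-distances. No indels by
    default (``indel_rate`` adds geometric-length deletions/insertions).
    Defaults give clearly clusterable families: within-identity around
    0.85, between-identity at the random background for a 20-letter
    alphabet.
    """

    n_families: int = 5
    members_per_family: int = 8
    root_length: int = 150
    within_rate: float = 0.08
    between_rate: float = 1.0
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_rate", "between_rate", "indel_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i, ch in enumerate(out):
        if rng.random() < rate:
            alternatives = _RESIDUES.replace(ch, "")
            out[i] = alternatives[int(rng.integers(0, len(alternatives)))]
    return "".join(out)


def _indel(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = seq
    if rng.random() < rate:  # one deletion
        length = min(len(out) - 1, 1 + int(rng.geometric(0.5)))
        pos = int(rng.integers(0, len(out) - length))
        out = out[:pos] + out[pos + length :]
    if rng.random() < rate:  # one insertion
        length = 1 + int(rng.geometric(0.5))
        ins = "".join(
            _RESIDUES[int(rng.integers(0, 20))] for _ in range(length)
        )
        pos = int(rng.integers(0, len(out) + 1))
        out = out[:pos] + ins + out[pos:]
    return out


def simulate_sequence_families(spec: SeqSimSpec) -> list[SeqRecord]:
    """Protein records whose ids encode their family (``F00_m000`` ...)."""
    rng = np.random.default_rng(spec.seed)
    ancestor = "".join(
        _RESIDUES[int(rng.integers(0, 20))] for _ in range(spec.root_length)
    )
    records: list[SeqRecord] = []
    for f in range(spec.n_families):
        root = _mutate(rng, ancestor, spec.between_rate)
        for m in range(spec.members_per_family):
            seq = _mutate(rng, root, spec.within_rate)
            seq = _indel(rng, seq, spec.indel_rate)
            records.append(SeqRecord(id=f"F{f:02d}_m{m:03d}", residues=seq))
    return records
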