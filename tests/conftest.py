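"""Shared fixtures: hand-built gene tables and random neighborhood sets."""

from __future__ import annotations

import numpy as np
import pytest

from domaincensus.genome_io import GeneRecord, Neighborhood


def make_gene(
    gene_no: int,
    domains: tuple[str, ...],
    genome_id: str = "G1",
    genus: str = "Alpha",
    contig_id: str = "c1",
    strand: str = "+",
) -> GeneRecord:
    return GeneRecord(
        genome_id=genome_id,
        genus=genus,
        contig_id=contig_id,
        gene_id=f"{genome_id}_g{gene_no:03d}",
        start=gene_no * 1000 + 1,
        end=gene_no * 1000 + 900,
        strand=strand,
        domains=domains,
    )


def make_neighborhood(
    domain_lists: list[tuple[str, ...]],
    genus: str = "Alpha",
    genome_id: str = "G1",
    anchor_index: int = 0,
    w: int = 50,
) -> Neighborhood:
    genes = tuple(
        make_gene(i, doms, genome_id=genome_id, genus=genus)
        for i, doms in enumerate(domain_lists)
    )
    return Neighborhood(
        genome_id=genome_id,
        genus=genus,
        contig_id="c1",
        anchor_gene_id=genes[anchor_index].gene_id,
        genes=genes,
        w=w,
    )


def random_neighborhoods(
    rng: np.random.Generator,
    n_nbhds: int,
    n_genera: int = 3,
    pool: tuple[str, ...] = tuple("ABCDEFG"),
) -> list[Neighborhood]:
    """Random windows with 0-3 domains per gene, for oracle comparisons."""
    out = []
    for k in range(n_nbhds):
        n_genes = int(rng.integers(3, 12))
        lists = [
            tuple(
                str(pool[int(rng.integers(0, len(pool)))])
                for _ in range(int(rng.integers(0, 4)))
            )
            for _ in range(n_genes)
        ]
        genus = f"genus{int(rng.integers(0, n_genera))}"
        out.append(
            make_neighborhood(lists, genus=genus, genome_id=f"G{k}", anchor_index=0)
        )
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
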