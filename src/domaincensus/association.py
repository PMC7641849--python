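"""The 1/(n+1) domain-association statistic and its hierarchical averages.

For any pair of domains observed within one genomic neighborhood, the
association is scored as ``1/(n+1)``, where ``n`` is the number of domain
occurrences encoded by distinct genes lying strictly between the two pair
members in coordinate order. Adjacent genes (and domain fusions on a single
gene) score 1; the score decays with operonic distance.

Scores are then averaged hierarchically: first across the neighborhoods
within each genus, then across genera, so that heavily sequenced genera do
not dominate the overall association value.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome_io import Neighborhood

__all__ = [
    "pair_score",
    "intervening_count",
    "neighborhood_pair_score",
    "neighborhood_pair_scores",
    "AssociationTable",
    "aggregate",
]


def pair_score(n: int) -> Fraction:
    """Association score 1/(n+1) for ``n`` intervening domains, exact."""
    if n < 0:
        raise ValueError("intervening count must be >= 0")
    return Fraction(1, n + 1)


def _gene_order(nbhd: Neighborhood) -> dict[str, int]:
    return {g.gene_id: i for i, g in enumerate(nbhd.genes)}


def intervening_count(
    nbhd: Neighborhood, gene_a: str, gene_b: str, domain_a: str, domain_b: str
) -> int:
    """Number of domain occurrences on genes strictly between two genes.

    Domains, not genes, are counted: a gene between the pair carrying two
    domains contributes 2, a gene with no annotated domain contributes 0.
    When both domains sit on the same gene (a fusion), n = 0.
    """
    order = _gene_order(nbhd)
    for gid, dom in ((gene_a, domain_a), (gene_b, domain_b)):
        if gid not in order:
            raise ValueError(f"gene {gid!r} not in neighborhood")
        if dom not in nbhd.genes[order[gid]].domains:
            raise ValueError(f"domain {dom!r} not on gene {gid!r}")
    i, j = sorted((order[gene_a], order[gene_b]))
    return sum(len(nbhd.genes[k].domains) for k in range(i + 1, j))


def neighborhood_pair_score(
    nbhd: Neighborhood, domain_a: str, domain_b: str
) -> Fraction | None:
    """Score for one domain pair within one neighborhood, or None if absent.

    When either domain occurs more than once the closest pair of occurrences
    (maximum score, i.e. tightest linkage) is used. A self-pair (domain_a ==
    domain_b) is scored only when the domain occurs on at least two distinct
    genes.
    """
    scores = neighborhood_pair_scores(nbhd)
    key = tuple(sorted((domain_a, domain_b)))
    return scores.get(key)


def neighborhood_pair_scores(nbhd: Neighborhood) -> dict[tuple[str, str], Fraction]:
    """Best (closest-occurrence) score for every domain pair in a window.

    Returns a mapping from the canonical (lexicographically sorted) domain
    pair to its 1/(n+1) score within this neighborhood.
    """
    # occurrences as (gene index in coordinate order, domain)
    occ: list[tuple[int, str]] = []
    for gi, gene in enumerate(nbhd.genes):
        for dom in gene.domains:
            occ.append((gi, dom))
    counts = [len(g.domains) for g in nbhd.genes]
    prefix = [0]
    for c in counts:
        prefix.append(prefix[-1] + c)

    best: dict[tuple[str, str], int] = {}  # pair -> minimal n
    for a in range(len(occ)):
        gi, da = occ[a]
        for b in range(a + 1, len(occ)):
            gj, db = occ[b]
            if da == db and gi == gj:
                continue  # a self-pair needs two distinct genes
            if gi == gj:
                n = 0
            else:
                i, j = sorted((gi, gj))
                n = prefix[j] - prefix[i + 1]
            key = (da, db) if da <= db else (db, da)
            if key not in best or n < best[key]:
                best[key] = n
    return {pair: pair_score(n) for pair, n in best.items()}


@dataclass
class AssociationTable:
    """Per-genus and overall association means for each domain pair.

    ``genus_means`` maps pair -> {genus: mean score over the genus'
    neighborhoods containing the pair}; ``support`` carries the matching
    neighborhood counts. ``overall`` is the across-genera average.
    """

    genus_means: dict[tuple[str, str], dict[str, Fraction]]
    support: dict[tuple[str, str], dict[str, int]]
    overall: dict[tuple[str, str], Fraction]

    def overall_frame(self) -> pd.DataFrame:
        rows = [
            {
                "domain_a": a,
                "domain_b": b,
                "overall_mean": float(m),
                "n_genera": len(self.genus_means[(a, b)]),
            }
            for (a, b), m in sorted(self.overall.items())
        ]
        return pd.DataFrame(
            rows, columns=["domain_a", "domain_b", "overall_mean", "n_genera"]
        )

    def genus_frame(self) -> pd.DataFrame:
        rows = [
            {
                "domain_a": a,
                "domain_b": b,
                "genus": genus,
                "genus_mean": float(m),
                "n_neighborhoods": self.support[(a, b)][genus],
            }
            for (a, b), by_genus in sorted(self.genus_means.items())
            for genus, m in sorted(by_genus.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["domain_a", "domain_b", "genus", "genus_mean", "n_neighborhoods"],
        )

    def to_tsv(self, overall_path, genus_path=None) -> None:
        self.overall_frame().to_csv(overall_path, sep="\t", index=False)
        if genus_path is not None:
            self.genus_frame().to_csv(genus_path, sep="\t", index=False)

    def top_pairs(self, k: int) -> list[tuple[tuple[str, str], float]]:
        """The k highest overall means; ties broken by lexicographic pair."""
        ranked = sorted(self.overall.items(), key=lambda kv: (-kv[1], kv[0]))
        return [(pair, float(m)) for pair, m in ranked[:k]]


def aggregate(
    nbhds: Sequence[Neighborhood], *, genus_weighting: str = "uniform"
) -> AssociationTable:
    """Two-level average of neighborhood pair scores.

    For each pair, the genus mean averages the pair's score over the genus'
    neighborhoods in which the pair co-occurs (absence is not counted as
    zero), and the overall mean averages the genus means over genera with at
    least one such neighborhood. ``genus_weighting="count"`` instead weights
    each genus mean by its neighborhood count (a pooled-within-genera mean).

    All arithmetic is exact (rational) until export.
    """
    if genus_weighting not in ("uniform", "count"):
        raise ValueError(f"unknown genus weighting {genus_weighting!r}")
    sums: dict[tuple[str, str], dict[str, Fraction]] = {}
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for nb in nbhds:
        for pair, score in neighborhood_pair_scores(nb).items():
            sums.setdefault(pair, {}).setdefault(nb.genus, Fraction(0))
            sums[pair][nb.genus] += score
            counts.setdefault(pair, {}).setdefault(nb.genus, 0)
            counts[pair][nb.genus] += 1

    genus_means: dict[tuple[str, str], dict[str, Fraction]] = {}
    overall: dict[tuple[str, str], Fraction] = {}
    for pair, by_genus in sums.items():
        means = {
            genus: total / counts[pair][genus] for genus, total in by_genus.items()
        }
        genus_means[pair] = means
        if genus_weighting == "uniform":
            overall[pair] = sum(means.values(), Fraction(0)) / len(means)
        else:
            total_n = sum(counts[pair].values())
            overall[pair] = (
                sum(by_genus.values(), Fraction(0)) / total_n
            )
    return AssociationTable(genus_means=genus_means, support=counts, overall=overall)
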