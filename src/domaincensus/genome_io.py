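"""Annotated gene tables and anchor-centered genomic neighborhoods.

The unit of analysis throughout the package is a *neighborhood*: the window
of genes surrounding a gene that carries a designated anchor domain (for
example EVE or DCD) on a single contig. Gene tables arrive as TSV with one
row per gene carrying genome, genus, contig, coordinates, strand and an
ordered (N->C) list of domain identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GeneRecord",
    "Neighborhood",
    "GENE_TABLE_COLUMNS",
    "read_gene_table",
    "write_gene_table",
    "extract_neighborhoods",
    "composition_key",
    "deduplicate_neighborhoods",
    "write_neighborhoods",
]

GENE_TABLE_COLUMNS = (
    "genome_id",
    "genus",
    "contig_id",
    "gene_id",
    "start",
    "end",
    "strand",
    "domains",
)

_STRANDS = {"+", "-", "−"}  # accept the unicode minus on read


class GeneTableError(ValueError):
    """Malformed gene table content."""


@dataclass(frozen=True)
class GeneRecord:
    """A single annotated gene.

    Coordinates are 1-based inclusive (GenBank convention). ``domains`` is
    the ordered list of domain identifiers encoded by the gene, N- to
    C-terminal; it may be empty for genes with no recognized domain.
    """

    genome_id: str
    genus: str
    contig_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    domains: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GeneTableError(
                f"gene {self.gene_id!r}: start ({self.start}) > end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise GeneTableError(
                f"gene {self.gene_id!r}: unknown strand symbol {self.strand!r}"
            )
        if any(d == "" for d in self.domains):
            raise GeneTableError(f"gene {self.gene_id!r}: empty domain identifier")


@dataclass(frozen=True)
class Neighborhood:
    """An ordered window of genes around an anchor-domain gene.

    ``genes`` is sorted by start coordinate and never crosses a contig
    boundary; with half-width ``w`` it holds at most ``w`` genes on each
    side of the anchor.
    """

    genome_id: str
    genus: str
    contig_id: str
    anchor_gene_id: str
    genes: tuple[GeneRecord, ...]
    w: int

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if self.anchor_gene_id not in ids:
            raise ValueError("anchor gene not contained in neighborhood")
        if any(g.contig_id != self.contig_id for g in self.genes):
            raise ValueError("neighborhood spans multiple contigs")
        if len(self.genes) > 2 * self.w + 1:
            raise ValueError("neighborhood exceeds window size")

    @property
    def anchor_index(self) -> int:
        return next(
            i for i, g in enumerate(self.genes) if g.gene_id == self.anchor_gene_id
        )


def _parse_domains(cell: object) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return ()
    text = str(cell).strip()
    if not text:
        return ()
    return tuple(part.strip() for part in text.split(","))


def read_gene_table(path, *, zero_based: bool = False) -> list[GeneRecord]:
    """Read a TSV gene table into a list of :class:`GeneRecord`.

    Parameters
    ----------
    path : str, Path or file-like
        TSV with header ``genome_id, genus, contig_id, gene_id, start, end,
        strand, domains``; the ``domains`` column is a comma-joined list and
        may be empty.
    zero_based : bool
        Declare the source as 0-based half-open; coordinates are converted
        to the 1-based inclusive convention used internally.

    Raises
    ------
    GeneTableError
        On a malformed row, naming the offending line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise GeneTableError(f"gene table missing columns: {missing}")
    records: list[GeneRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        try:
            start = int(row.start)
            end = int(row.end)
        except ValueError as exc:
            raise GeneTableError(f"line {line_no}: non-integer coordinate") from exc
        if zero_based:
            start, end = start + 1, end
        strand = str(row.strand).strip()
        if strand == "−":
            strand = "-"
        if strand not in _STRANDS:
            raise GeneTableError(f"line {line_no}: unknown strand symbol {strand!r}")
        try:
            records.append(
                GeneRecord(
                    genome_id=row.genome_id,
                    genus=row.genus,
                    contig_id=row.contig_id,
                    gene_id=row.gene_id,
                    start=start,
                    end=end,
                    strand=strand,
                    domains=_parse_domains(row.domains),
                )
            )
        except GeneTableError as exc:
            raise GeneTableError(f"line {line_no}: {exc}") from exc
    seen: dict[tuple[str, str], int] = {}
    for rec in records:
        key = (rec.genome_id, rec.gene_id)
        if key in seen:
            raise GeneTableError(
                f"duplicate gene_id {rec.gene_id!r} within genome {rec.genome_id!r}"
            )
        seen[key] = 1
    return records


def write_gene_table(records: Iterable[GeneRecord], path) -> None:
    """Write gene records as a TSV gene table (inverse of read_gene_table)."""
    rows = [
        {
            "genome_id": r.genome_id,
            "genus": r.genus,
            "contig_id": r.contig_id,
            "gene_id": r.gene_id,
            "start": r.start,
            "end": r.end,
            "strand": r.strand,
            "domains": ",".join(r.domains),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(GENE_TABLE_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def extract_neighborhoods(
    genes: Sequence[GeneRecord], anchor_domain: str, w: int = 10
) -> list[Neighborhood]:
    """Extract one window of up to ``w`` genes on each side per anchor gene.

    Window membership is counted in genes (not base pairs), strand is
    ignored, and windows are truncated at contig ends: a neighborhood never
    crosses a contig boundary. Genes carrying ``anchor_domain`` but located
    on different contigs yield independent neighborhoods; a contig without
    the anchor yields none.
    """
    if w < 0:
        raise ValueError("window half-width must be >= 0")
    by_contig: dict[tuple[str, str], list[GeneRecord]] = {}
    for g in genes:
        by_contig.setdefault((g.genome_id, g.contig_id), []).append(g)
    out: list[Neighborhood] = []
    for (_, contig_id), contig_genes in by_contig.items():
        ordered = sorted(contig_genes, key=lambda g: (g.start, g.end, g.gene_id))
        for idx, gene in enumerate(ordered):
            if anchor_domain not in gene.domains:
                continue
            lo = max(0, idx - w)
            hi = min(len(ordered), idx + w + 1)
            out.append(
                Neighborhood(
                    genome_id=gene.genome_id,
                    genus=gene.genus,
                    contig_id=contig_id,
                    anchor_gene_id=gene.gene_id,
                    genes=tuple(ordered[lo:hi]),
                    w=w,
                )
            )
    return out


def composition_key(nbhd: Neighborhood) -> tuple[str, ...]:
    """Domain identifiers concatenated over the window's genes in coordinate
    order — two neighborhoods with identical domain content share a key."""
    return tuple(d for g in nbhd.genes for d in g.domains)


def deduplicate_neighborhoods(
    nbhds: Sequence[Neighborhood], *, per_genus: bool = False
) -> list[Neighborhood]:
    """Keep the first neighborhood per unique domain composition.

    Deduplication is global across the input by default, mirroring a census
    of genomes with unique domain compositions; ``per_genus=True`` scopes
    the uniqueness to each genus instead. Output order is stable.
    """
    seen: set = set()
    kept: list[Neighborhood] = []
    for nb in nbhds:
        key = (nb.genus, composition_key(nb)) if per_genus else composition_key(nb)
        if key in seen:
            continue
        seen.add(key)
        kept.append(nb)
    return kept


def write_neighborhoods(nbhds: Iterable[Neighborhood], path) -> None:
    """Export neighborhoods as TSV with one row per (neighborhood, gene)."""
    rows = []
    for k, nb in enumerate(nbhds):
        for g in nb.genes:
            rows.append(
                {
                    "neighborhood_id": k,
                    "genome_id": nb.genome_id,
                    "genus": nb.genus,
                    "contig_id": nb.contig_id,
                    "anchor_gene_id": nb.anchor_gene_id,
                    "gene_id": g.gene_id,
                    "start": g.start,
                    "end": g.end,
                    "strand": g.strand,
                    "domains": ",".join(g.domains),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
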