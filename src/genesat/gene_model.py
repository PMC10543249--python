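"""Gene regions and position-based assignment of variants to genes.

Genes are modelled as TSS–TES intervals (1-based, inclusive on both ends
internally). BED input (0-based half-open) and GTF input (1-based
inclusive, ``gene`` features only) are both normalized to that convention.
A QC-passed variant belongs to a gene when it falls inside the gene's
(optionally padded) interval on the same chromosome; variants may belong
to several overlapping genes. Genes with fewer than ``min_snps`` member
variants are dropped, since a single variant cannot support a SNP-set
test beyond its own marginal test.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pyranges as pr

from .sumstats import SummaryStatRecord, normalize_chrom

__all__ = ["GeneRegion", "GeneAssignment", "load_genes", "assign_snps"]


class InputError(ValueError):
    pass


@dataclass
class GeneRegion:
    """A named genomic interval, 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if self.strand not in ("+", "-", "unknown"):
            self.strand = "unknown"
        if self.start > self.end:
            raise InputError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise InputError(f"gene {self.gene_id}: start {self.start} < 1")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GeneAssignment:
    """A gene plus its member variants, sorted by position (ties by rsid)."""

    gene: GeneRegion
    members: list[SummaryStatRecord] = field(default_factory=list)

    @property
    def gene_id(self) -> str:
        return self.gene.gene_id

    def __len__(self) -> int:
        return len(self.members)


def load_genes(path: str | Path, format: str | None = None) -> list[GeneRegion]:
    """Read gene regions from BED4+ or GTF.

    ``format`` is ``"bed"`` or ``"gtf"``; if None it is inferred from the
    file suffix. BED is 0-based half-open and is converted to 1-based
    inclusive; GTF is read from ``gene`` feature rows (``gene_id``
    attribute, falling back to ``gene_name``). Duplicated gene identifiers
    are rejected.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "gtf" if suffix in (".gtf", ".gff") else "bed"
    format = format.lower()

    genes: list[GeneRegion] = []
    if format == "bed":
        df = pr.read_bed(str(path)).df
        if "Name" not in df.columns:
            raise InputError(f"BED file {path} needs at least 4 columns (name in column 4)")
        for row in df.itertuples(index=False):
            genes.append(
                GeneRegion(
                    gene_id=str(row.Name),
                    chrom=str(row.Chromosome),
                    start=int(row.Start) + 1,  # 0-based half-open -> 1-based inclusive
                    end=int(row.End),
                    strand=str(getattr(row, "Strand", "unknown")),
                )
            )
    elif format == "gtf":
        df = pr.read_gtf(str(path)).df
        df = df[df["Feature"] == "gene"]
        if df.empty:
            raise InputError(f"GTF file {path} contains no 'gene' feature rows")
        name_col = "gene_id" if "gene_id" in df.columns else "gene_name"
        for row in df.itertuples(index=False):
            genes.append(
                GeneRegion(
                    gene_id=str(getattr(row, name_col)),
                    chrom=str(row.Chromosome),
                    start=int(row.Start) + 1,  # pyranges stores GTF 0-based too
                    end=int(row.End),
                    strand=str(getattr(row, "Strand", "unknown")),
                )
            )
    else:
        raise InputError(f"unknown gene file format: {format!r}")

    seen: dict[str, int] = {}
    for g in genes:
        seen[g.gene_id] = seen.get(g.gene_id, 0) + 1
    dups = sorted(g for g, n in seen.items() if n > 1)
    if dups:
        raise InputError(f"duplicate gene ids in {path}: {dups}")
    return genes


def assign_snps(
    records: Iterable[SummaryStatRecord],
    genes: Sequence[GeneRegion],
    padding_bp: int = 0,
    min_snps: int = 2,
) -> tuple[list[GeneAssignment], pd.DataFrame]:
    """Assign variants to genes by position.

    A variant belongs to a gene iff ``start - padding_bp <= pos <=
    end + padding_bp`` on the same chromosome. Shared variants go to every
    overlapping gene. Returns the assignments with ≥ ``min_snps`` members
    plus a report of dropped genes (gene_id, n_snps, reason).

    The result is independent of input record order: members are sorted by
    position, ties broken by rsid.
    """
    by_chrom: dict[str, list[SummaryStatRecord]] = {}
    for rec in records:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    for recs in by_chrom.values():
        recs.sort(key=lambda r: (r.pos, r.rsid))

    kept: list[GeneAssignment] = []
    dropped: list[tuple[str, int, str]] = []
    for gene in genes:
        recs = by_chrom.get(gene.chrom, [])
        positions = [r.pos for r in recs]
        lo = bisect_left(positions, gene.start - padding_bp)
        hi = bisect_right(positions, gene.end + padding_bp)
        members = recs[lo:hi]
        if len(members) < min_snps:
            dropped.append((gene.gene_id, len(members), f"fewer than {min_snps} SNPs"))
        else:
            kept.append(GeneAssignment(gene=gene, members=list(members)))
    report = pd.DataFrame(dropped, columns=["gene_id", "n_snps", "reason"])
    return kept, report
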