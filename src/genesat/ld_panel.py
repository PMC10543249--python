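"""LD reference panels: per-gene correlation matrices from genotype data.

The reference panel (e.g. a 1000 Genomes European subset) supplies
genotype dosages from which per-gene linkage-disequilibrium matrices R
are estimated as Pearson correlations between dosage vectors. GWAS
variants are matched to panel variants at the same position with the same
allele pair; when the GWAS effect allele is the panel's *reference*
allele the Z-score sign is flipped so that every z counts the panel's
alternate allele. One SNP of each perfectly correlated pair is pruned so
that R is numerically well conditioned. Processed per-gene (z, R) pairs
are saved in portable per-chromosome text bundles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .gene_model import GeneAssignment, GeneRegion
from .sumstats import normalize_chrom

__all__ = [
    "PanelVariant",
    "LDMatrix",
    "GeneSnpSet",
    "HarmonizedSet",
    "load_panel",
    "harmonize",
    "compute_ld",
    "prune_perfect",
    "build_bundles",
    "read_bundles",
]

# cyvcf2 gt_types codes: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
_GT_TO_DOSAGE = {0: 0.0, 1: 1.0, 2: np.nan, 3: 2.0}


class InputError(ValueError):
    pass


class EmptyLDError(ValueError):
    """No usable (polymorphic) variants remain for LD estimation."""


@dataclass
class PanelVariant:
    """One biallelic panel SNV with per-sample ALT-allele dosages."""

    chrom: str
    pos: int
    rsid: str
    ref_allele: str
    alt_allele: str
    dosages: np.ndarray  # float; np.nan marks missing genotypes

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        self.dosages = np.asarray(self.dosages, dtype=float)

    @property
    def allele_pair(self) -> frozenset[str]:
        return frozenset((self.ref_allele, self.alt_allele))


@dataclass
class LDMatrix:
    """Pearson correlation matrix over an ordered SNP list."""

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)

    @property
    def m(self) -> int:
        return len(self.snp_ids)

    def check(self, eig_tol: float = 1e-8) -> None:
        r = self.r
        if r.shape != (self.m, self.m):
            raise ValueError("LD matrix shape does not match SNP list")
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-12):
            raise ValueError("LD matrix diagonal is not 1")
        if np.nanmax(np.abs(r)) > 1 + 1e-12:
            raise ValueError("LD entries outside [-1, 1]")
        if np.linalg.eigvalsh((r + r.T) / 2).min() < -eig_tol:
            raise ValueError("LD matrix is not PSD within tolerance")


@dataclass
class GeneSnpSet:
    """Harmonized per-gene Z-vector with its LD matrix; the test unit.

    ``snps`` carries the bookkeeping table (rsid, pos, effect/other allele
    as harmonized, z) aligned with ``ld.snp_ids``; ``provenance`` counts
    what happened during matching and pruning.
    """

    gene_id: str
    chrom: str
    z: np.ndarray
    ld: LDMatrix
    snps: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if len(self.z) != self.ld.m:
            raise ValueError("z and LD matrix are not index-aligned")

    @property
    def m(self) -> int:
        return len(self.z)

    @property
    def midpoint(self) -> int:
        if self.start is not None and self.end is not None:
            return (self.start + self.end) // 2
        return int(np.median(self.snps["pos"]))


def load_panel(
    vcf_path: str | Path,
    region: tuple[str, int, int] | None = None,
    sample_subset: Sequence[str] | None = None,
) -> tuple[list[PanelVariant], dict]:
    """Read biallelic SNVs from a VCF reference panel.

    ``region`` is (chrom, start, end), 1-based inclusive; None reads the
    whole file. Multi-allelic sites and indels are skipped and counted.
    Works on plain-text VCFs by streaming; an index is not required.
    Returns the variants plus a skip-count dict.
    """
    vcf_path = Path(vcf_path)
    if not vcf_path.exists():
        raise InputError(f"panel VCF not found: {vcf_path}")
    try:
        vcf = VCF(str(vcf_path), samples=list(sample_subset) if sample_subset else None)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad files
        raise InputError(f"unreadable VCF {vcf_path}: {exc}") from exc

    want_chrom = normalize_chrom(region[0]) if region else None
    variants: list[PanelVariant] = []
    skipped = {"multiallelic": 0, "indel_or_other": 0, "outside_region": 0}
    for rec in vcf:
        if region is not None:
            if normalize_chrom(rec.CHROM) != want_chrom or not (
                region[1] <= rec.POS <= region[2]
            ):
                skipped["outside_region"] += 1
                continue
        if len(rec.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        if not rec.is_snp:
            skipped["indel_or_other"] += 1
            continue
        dosages = np.array([_GT_TO_DOSAGE[g] for g in rec.gt_types], dtype=float)
        variants.append(
            PanelVariant(
                chrom=rec.CHROM,
                pos=rec.POS,
                rsid=rec.ID or f"{rec.CHROM}:{rec.POS}",
                ref_allele=rec.REF.upper(),
                alt_allele=rec.ALT[0].upper(),
                dosages=dosages,
            )
        )
    vcf.close()
    return variants, skipped


@dataclass
class HarmonizedSet:
    """Matched (GWAS, panel) variant pairs for one gene, position-ordered."""

    gene: GeneRegion
    variants: list[PanelVariant]
    z: np.ndarray
    flipped: np.ndarray  # bool per kept variant
    counts: dict

    @property
    def m(self) -> int:
        return len(self.variants)


def harmonize(assignment: GeneAssignment, panel_variants: Sequence[PanelVariant]) -> HarmonizedSet:
    """Match a gene's GWAS variants to panel variants and orient Z-scores.

    Matching is by (pos, allele pair). If the GWAS effect allele equals the
    panel ALT (counted) allele, z is kept; if it equals the panel REF
    allele, the sign is flipped; incompatible allele pairs are dropped and
    counted. Output preserves position order. Strand-complement matching
    is deliberately not attempted (ambiguous SNPs were removed upstream).
    """
    panel_by_pos: dict[int, list[PanelVariant]] = {}
    for pv in panel_variants:
        if pv.chrom == assignment.gene.chrom:
            panel_by_pos.setdefault(pv.pos, []).append(pv)

    kept_variants: list[PanelVariant] = []
    zs: list[float] = []
    flips: list[bool] = []
    counts = {"matched": 0, "flipped": 0, "dropped_unmatched": 0, "dropped_incompatible": 0}
    for rec in assignment.members:
        if rec.z is None:
            raise ValueError(f"record {rec.rsid} has no Z-score; run compute_z first")
        candidates = panel_by_pos.get(rec.pos, [])
        match = next((pv for pv in candidates if pv.allele_pair == rec.allele_pair), None)
        if match is None:
            if candidates:
                counts["dropped_incompatible"] += 1
            else:
                counts["dropped_unmatched"] += 1
            continue
        if rec.effect_allele == match.alt_allele:
            flip = False
        else:  # effect allele is the panel REF allele
            flip = True
        counts["matched"] += 1
        counts["flipped"] += int(flip)
        kept_variants.append(match)
        zs.append(-rec.z if flip else rec.z)
        flips.append(flip)
    return HarmonizedSet(
        gene=assignment.gene,
        variants=kept_variants,
        z=np.array(zs, dtype=float),
        flipped=np.array(flips, dtype=bool),
        counts=counts,
    )


def compute_ld(variants: Sequence[PanelVariant]) -> tuple[LDMatrix, list[int]]:
    """Pairwise Pearson correlation of dosage vectors.

    Missing genotypes are handled pairwise-complete. Monomorphic variants
    (zero dosage variance over non-missing samples) are dropped first and
    their indices returned. The diagonal is set to exactly 1.
    """
    if len(variants) < 2:
        raise EmptyLDError("need at least 2 variants for an LD matrix")
    dos = pd.DataFrame({i: v.dosages for i, v in enumerate(variants)})
    variances = dos.var(axis=0, ddof=1)
    mono_idx = [i for i in range(len(variants)) if not variances.iloc[i] > 0]
    keep = [i for i in range(len(variants)) if i not in set(mono_idx)]
    if len(keep) < 2:
        raise EmptyLDError("fewer than 2 polymorphic variants")
    corr = dos[keep].corr(method="pearson").to_numpy()  # pairwise-complete
    corr = np.clip((corr + corr.T) / 2, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    snp_ids = [variants[i].rsid for i in keep]
    return LDMatrix(snp_ids=snp_ids, r=corr), mono_idx


def _greedy_prune(r: np.ndarray, r_max: float) -> list[int]:
    """Indices kept by greedy position-order pruning at |r| >= r_max."""
    m = r.shape[0]
    kept: list[int] = []
    for j in range(m):
        if all(abs(r[i, j]) < r_max for i in kept):
            kept.append(j)
    return kept


def prune_perfect(gene_set: GeneSnpSet, r_max: float = 0.9999) -> GeneSnpSet:
    """Remove the later-position SNP of every perfectly correlated pair.

    Scans pairs in position order and, whenever |r_ij| ≥ ``r_max``, drops
    the later SNP; the survivor set is re-checked so no remaining pair
    reaches the threshold (idempotent projection). Raises
    ``EmptyLDError`` if fewer than 2 SNPs survive.
    """
    kept = _greedy_prune(gene_set.ld.r, r_max)
    n_pruned = gene_set.m - len(kept)
    if len(kept) < 2:
        raise EmptyLDError(
            f"gene {gene_set.gene_id}: pruning at |r|>={r_max} leaves {len(kept)} SNP(s)"
        )
    r = gene_set.ld.r[np.ix_(kept, kept)]
    off = np.abs(r[~np.eye(len(kept), dtype=bool)])
    assert off.size == 0 or off.max() < r_max, "pruning left a perfectly correlated pair"
    provenance = dict(gene_set.provenance)
    provenance["pruned"] = provenance.get("pruned", 0) + n_pruned
    return GeneSnpSet(
        gene_id=gene_set.gene_id,
        chrom=gene_set.chrom,
        z=gene_set.z[kept],
        ld=LDMatrix(snp_ids=[gene_set.ld.snp_ids[i] for i in kept], r=r),
        snps=gene_set.snps.iloc[kept].reset_index(drop=True),
        provenance=provenance,
        start=gene_set.start,
        end=gene_set.end,
    )


def build_gene_set(harmonized: HarmonizedSet, r_max: float = 0.9999) -> GeneSnpSet:
    """LD estimation + pruning for one harmonized gene.

    Raises ``EmptyLDError`` when fewer than 2 usable SNPs remain.
    """
    if harmonized.m < 2:
        raise EmptyLDError(
            f"gene {harmonized.gene.gene_id}: {harmonized.m} harmonized SNP(s)"
        )
    ld, mono_idx = compute_ld(harmonized.variants)
    keep = [i for i in range(harmonized.m) if i not in set(mono_idx)]
    snps = pd.DataFrame(
        {
            "rsid": [harmonized.variants[i].rsid for i in keep],
            "pos": [harmonized.variants[i].pos for i in keep],
            "effect_allele": [harmonized.variants[i].alt_allele for i in keep],
            "other_allele": [harmonized.variants[i].ref_allele for i in keep],
            "z": harmonized.z[keep],
        }
    )
    gs = GeneSnpSet(
        gene_id=harmonized.gene.gene_id,
        chrom=harmonized.gene.chrom,
        z=harmonized.z[keep],
        ld=ld,
        snps=snps,
        provenance={**harmonized.counts, "monomorphic": len(mono_idx)},
        start=harmonized.gene.start,
        end=harmonized.gene.end,
    )
    return prune_perfect(gs, r_max=r_max)


# ---------------------------------------------------------------------------
# On-disk bundles: one directory per chromosome, delimited text per gene,
# plus a manifest with counts and checksums. A portable replacement for
# per-chromosome binary workspace files.
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def build_bundles(gene_sets: Iterable[GeneSnpSet], out_dir: str | Path) -> Path:
    """Write per-chromosome bundles of (SNP table, LD matrix) per gene.

    Layout::

        out_dir/manifest.json
        out_dir/chr<k>/<gene>.snps.tsv
        out_dir/chr<k>/<gene>.ld.tsv

    Floats are written at 17 significant digits so a round-trip read
    reproduces values bit-exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"chromosomes": {}, "genes": {}}
    for gs in gene_sets:
        chrom_dir = out_dir / f"chr{gs.chrom}"
        chrom_dir.mkdir(exist_ok=True)
        snp_path = chrom_dir / f"{gs.gene_id}.snps.tsv"
        ld_path = chrom_dir / f"{gs.gene_id}.ld.tsv"
        snps = gs.snps.copy()
        snps["z"] = [_FLOAT_FMT % v for v in gs.z]
        snps.to_csv(snp_path, sep="\t", index=False)
        np.savetxt(ld_path, gs.ld.r, fmt=_FLOAT_FMT, delimiter="\t")
        entry = {
            "chrom": gs.chrom,
            "m": gs.m,
            "start": gs.start,
            "end": gs.end,
            "provenance": gs.provenance,
            "snps_sha256": _sha256(snp_path),
            "ld_sha256": _sha256(ld_path),
        }
        manifest["genes"][gs.gene_id] = entry
        manifest["chromosomes"].setdefault(gs.chrom, []).append(gs.gene_id)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out_dir


def read_bundles(bundle_dir: str | Path) -> list[GeneSnpSet]:
    """Read bundles written by :func:`build_bundles`; round-trip exact."""
    bundle_dir = Path(bundle_dir)
    manifest_path = bundle_dir / "manifest.json"
    if not manifest_path.exists():
        raise InputError(f"no manifest.json in {bundle_dir}")
    manifest = json.loads(manifest_path.read_text())
    gene_sets: list[GeneSnpSet] = []
    for chrom in sorted(manifest["chromosomes"]):
        for gene_id in manifest["chromosomes"][chrom]:
            entry = manifest["genes"][gene_id]
            chrom_dir = bundle_dir / f"chr{chrom}"
            snps = pd.read_csv(
                chrom_dir / f"{gene_id}.snps.tsv", sep="\t", float_precision="round_trip"
            )
            r = np.loadtxt(chrom_dir / f"{gene_id}.ld.tsv", delimiter="\t", ndmin=2)
            z = snps["z"].to_numpy(dtype=float)
            gene_sets.append(
                GeneSnpSet(
                    gene_id=gene_id,
                    chrom=chrom,
                    z=z,
                    ld=LDMatrix(snp_ids=list(snps["rsid"].astype(str)), r=r),
                    snps=snps,
                    provenance=entry.get("provenance", {}),
                    start=entry.get("start"),
                    end=entry.get("end"),
                )
            )
    return gene_sets
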