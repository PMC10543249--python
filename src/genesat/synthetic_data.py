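"""Synthetic inputs with known ground truth for the whole pipeline.

Generates every artifact the pipeline consumes — LD structures, per-gene
Z-scores under the null (delta = 0) or an alternative (mean shift delta),
a diploid reference genotype panel written as VCF, consortium-style
summary-statistics files, gene annotations as BED, and negative-binomial
count matrices for the expression stage — all as pure functions of a
configuration including its seed.

Genotypes come from a latent-Gaussian threshold model: per haplotype a
correlated standard-normal vector is thresholded at the allele-frequency
quantile, and the two haplotype indicators are summed into a {0,1,2}
dosage. Realized dosage correlation is attenuated relative to the latent
target correlation (the threshold transform contracts dependence); the
pipeline estimates LD from the realized panel exactly as it would for
real data, so calibration analyses use the realized — not the target —
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ld_panel import LDMatrix, PanelVariant

__all__ = [
    "SimConfig",
    "DESimParams",
    "make_ld",
    "simulate_z",
    "simulate_panel",
    "write_vcf",
    "simulate_sumstats",
    "simulate_counts",
    "simulate_study",
]

# non-ambiguous allele pairs (ref, alt); strand-ambiguous A/T and C/G are
# never generated so the QC ambiguity filter does not eat simulated SNPs
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "T"))


@dataclass
class DESimParams:
    """Negative-binomial count simulation settings.

    ``n_per_group`` defaults to 3 vs 3, the design of the small
    case/control brain RNA-seq comparison this stage emulates.
    ``dispersion`` is the NB alpha (variance = mu + alpha mu^2).
    """

    n_per_group: int = 3
    true_lfc: float | Sequence[float] = 0.0
    dispersion: float = 0.1
    size_multiplier_range: tuple[float, float] = (0.7, 1.4)
    base_mean_log_mu: float = np.log(200.0)
    base_mean_log_sigma: float = 1.0


@dataclass
class SimConfig:
    """Study-level simulation settings for the GWAS side.

    Defaults describe the synthetic analog of the study conditions: a
    ~500-sample European-style reference panel (matching the 1000 Genomes
    phase-3 European subset size), AR(1) LD with r = 0.5, 10 SNPs per
    gene, common variants (MAF 0.05–0.5).
    """

    seed: int = 0
    n_genes: int = 50
    m_per_gene: int = 10
    ld_structure: str = "ar1"
    ld_r: float = 0.5
    ld_block_size: int = 5
    delta: dict[str, float] = field(default_factory=dict)  # gene_id -> per-SNP shift
    panel_n: int = 503
    maf_range: tuple[float, float] = (0.05, 0.5)
    se_range: tuple[float, float] = (0.02, 0.05)
    info_range: tuple[float, float] = (0.92, 1.0)
    chrom: str = "1"
    gene_spacing_bp: int = 100_000
    snp_spacing_bp: int = 100
    de: DESimParams = field(default_factory=DESimParams)

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5]: {self.maf_range}")
        if not (-1 < self.ld_r < 1):
            raise ValueError(f"ld_r must be in (-1, 1): {self.ld_r}")


def make_ld(structure: str, m: int, r: float = 0.5, block_size: int = 5) -> LDMatrix:
    """Construct a model LD matrix: ``ar1`` (r^|i-j|), ``block``
    (within-block r, between-block 0) or ``identity``."""
    if m < 2:
        raise ValueError("need m >= 2")
    if structure == "ar1":
        if not (-1 < r < 1):
            raise ValueError(f"ar1 parameter must be in (-1, 1): {r}")
        mat = r ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
    elif structure == "block":
        if not (-1 < r < 1):
            raise ValueError(f"block parameter must be in (-1, 1): {r}")
        blocks = np.arange(m) // block_size
        mat = np.where(np.equal.outer(blocks, blocks), r, 0.0)
        np.fill_diagonal(mat, 1.0)
    elif structure == "identity":
        mat = np.eye(m)
    else:
        raise ValueError(f"unknown LD structure: {structure!r}")
    ld = LDMatrix(snp_ids=[f"snp{i + 1}" for i in range(m)], r=mat)
    ld.check()
    return ld


def _sqrt_psd(R: np.ndarray, jitter: float = 1e-8) -> np.ndarray:
    w, V = np.linalg.eigh((R + R.T) / 2)
    if w.min() < -jitter:
        raise ValueError(f"correlation matrix not PSD beyond jitter: min eig {w.min()}")
    return V * np.sqrt(np.clip(w, 0.0, None))


def simulate_z(
    R: np.ndarray | LDMatrix,
    delta: float | Sequence[float],
    n_reps: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw Z-vectors from MVN(delta, R); shape (n_reps, m)."""
    r = R.r if isinstance(R, LDMatrix) else np.asarray(R, float)
    m = r.shape[0]
    delta = np.broadcast_to(np.asarray(delta, float), (m,))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = _sqrt_psd(r)
    return rng.standard_normal((n_reps, m)) @ L.T + delta[None, :]


def simulate_panel(
    R_target: np.ndarray | LDMatrix,
    mafs: Sequence[float],
    n_samples: int,
    seed: int | np.random.Generator,
    chrom: str = "1",
    positions: Sequence[int] | None = None,
    rsids: Sequence[str] | None = None,
    vcf_path: str | Path | None = None,
) -> tuple[list[PanelVariant], np.ndarray]:
    """Diploid genotypes from the latent-Gaussian threshold model.

    Per haplotype, a draw x ~ MVN(0, R_target) carries the alternate
    allele at SNP j when x_j < Phi^{-1}(maf_j); the dosage is the sum over
    the two haplotypes. The realized dosage correlation is attenuated
    relative to ``R_target``. Optionally writes the panel as a VCF.
    Returns (variants, samples-by-SNPs dosage matrix).
    """
    r = R_target.r if isinstance(R_target, LDMatrix) else np.asarray(R_target, float)
    m = r.shape[0]
    mafs = np.asarray(mafs, float)
    if mafs.shape != (m,):
        raise ValueError("mafs length must match R_target")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = _sqrt_psd(r)
    thresh = norm.ppf(mafs)
    hap1 = rng.standard_normal((n_samples, m)) @ L.T < thresh[None, :]
    hap2 = rng.standard_normal((n_samples, m)) @ L.T < thresh[None, :]
    dosage = (hap1.astype(int) + hap2.astype(int)).astype(float)

    if positions is None:
        positions = [1000 + 100 * j for j in range(m)]
    if rsids is None:
        rsids = [f"rs{j + 1}" for j in range(m)]
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    variants = [
        PanelVariant(
            chrom=chrom,
            pos=int(positions[j]),
            rsid=str(rsids[j]),
            ref_allele=_ALLELE_PAIRS[pair_idx[j]][0],
            alt_allele=_ALLELE_PAIRS[pair_idx[j]][1],
            dosages=dosage[:, j],
        )
        for j in range(m)
    ]
    if vcf_path is not None:
        sample_ids = [f"SAMPLE{i + 1}" for i in range(n_samples)]
        write_vcf(variants, sample_ids, vcf_path)
    return variants, dosage


_GT_STRINGS = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(
    variants: Sequence[PanelVariant], sample_ids: Sequence[str], path: str | Path
) -> Path:
    """Write panel variants as a minimal valid uncompressed VCF (GT only)."""
    path = Path(path)
    variants = sorted(variants, key=lambda v: (v.chrom, v.pos))
    chroms = []
    for v in variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        for v in variants:
            gts = "\t".join(
                _GT_STRINGS.get(d, "./.") if np.isfinite(d) else "./." for d in v.dosages
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.rsid}\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )
    return path


def _gene_layout(sim: SimConfig, g: int) -> tuple[str, int, list[int]]:
    """(gene_id, start, SNP positions) for gene index g."""
    gene_id = f"GENE{g + 1:04d}"
    start = 10_000 + g * sim.gene_spacing_bp
    positions = [start + j * sim.snp_spacing_bp for j in range(sim.m_per_gene)]
    return gene_id, start, positions


def simulate_sumstats(
    sim: SimConfig,
    out_dir: str | Path,
    prefix: str = "discovery",
    panel_dosages: dict[str, tuple[list[PanelVariant], np.ndarray]] | None = None,
    write_panel: bool = True,
) -> dict[str, Path]:
    """Write a complete synthetic GWAS input set with known ground truth.

    Per gene: a genotype panel is drawn (or reused from
    ``panel_dosages``), the realized panel LD is computed, per-SNP
    Z-scores are drawn from MVN(delta, realized LD) and converted to
    odds-ratio/standard-error pairs via OR = exp(z * se) with se uniform
    in ``sim.se_range``. The effect-allele column is randomly oriented to
    the panel REF or ALT allele (with the Z sign flipped accordingly) so
    the harmonization stage is genuinely exercised.

    Returns the paths written: summary statistics, gene BED, panel VCF
    (unless ``write_panel`` is False), and a gene -> delta truth table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(sim.seed)
    latent = make_ld(sim.ld_structure, sim.m_per_gene, r=sim.ld_r, block_size=sim.ld_block_size)

    rows = []
    bed_lines = []
    truth = []
    all_variants: list[PanelVariant] = []
    reuse = panel_dosages is not None
    panel_out: dict[str, tuple[list[PanelVariant], np.ndarray]] = (
        panel_dosages if reuse else {}
    )
    for g in range(sim.n_genes):
        gene_id, start, positions = _gene_layout(sim, g)
        end = positions[-1]
        bed_lines.append(f"{sim.chrom}\t{start - 1}\t{end}\t{gene_id}\t0\t+\n")
        if reuse:
            variants, dosage = panel_out[gene_id]
        else:
            mafs = rng.uniform(*sim.maf_range, size=sim.m_per_gene)
            rsids = [f"rs{g * sim.m_per_gene + j + 1}" for j in range(sim.m_per_gene)]
            variants, dosage = simulate_panel(
                latent, mafs, sim.panel_n, rng, chrom=sim.chrom,
                positions=positions, rsids=rsids,
            )
            panel_out[gene_id] = (variants, dosage)
        all_variants.extend(variants)

        realized = pd.DataFrame(dosage).corr().to_numpy()
        realized = np.clip((realized + realized.T) / 2, -1, 1)
        np.fill_diagonal(realized, 1.0)
        delta = sim.delta.get(gene_id, 0.0)
        z = simulate_z(realized, delta, 1, rng)[0]
        truth.append((gene_id, delta))

        se = rng.uniform(*sim.se_range, size=sim.m_per_gene)
        info = rng.uniform(*sim.info_range, size=sim.m_per_gene)
        flip_file = rng.random(sim.m_per_gene) < 0.5
        for j, v in enumerate(variants):
            z_file = -z[j] if flip_file[j] else z[j]
            ea = v.ref_allele if flip_file[j] else v.alt_allele
            oa = v.alt_allele if flip_file[j] else v.ref_allele
            rows.append(
                {
                    "SNP": v.rsid,
                    "CHR": v.chrom,
                    "BP": v.pos,
                    "A1": ea,
                    "A2": oa,
                    "OR": np.exp(z_file * se[j]),
                    "SE": se[j],
                    "INFO": info[j],
                }
            )

    paths: dict[str, Path] = {}
    sumstats_path = out_dir / f"{prefix}.sumstats.tsv"
    pd.DataFrame(rows).to_csv(sumstats_path, sep="\t", index=False, float_format="%.10g")
    paths["sumstats"] = sumstats_path

    genes_path = out_dir / "genes.bed"
    if not (reuse and genes_path.exists()):
        genes_path.write_text("".join(bed_lines))
    paths["genes"] = genes_path

    if write_panel and not reuse:
        vcf_path = out_dir / "panel.vcf"
        write_vcf(all_variants, [f"SAMPLE{i + 1}" for i in range(sim.panel_n)], vcf_path)
        paths["panel"] = vcf_path
    elif (out_dir / "panel.vcf").exists():
        paths["panel"] = out_dir / "panel.vcf"

    truth_path = out_dir / f"{prefix}.truth.tsv"
    pd.DataFrame(truth, columns=["gene_id", "delta"]).to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    paths["_panel_dosages"] = panel_out  # in-memory; for paired replication draws
    return paths


def simulate_counts(
    de_params: DESimParams, n_genes: int, seed: int | np.random.Generator
):
    """NB count matrix (genes x samples, cases then controls) + truth table.

    Mean model: mu[g, s] = base_mean[g] * size_mult[s] * 2^(lfc[g]) for
    cases, base_mean[g] * size_mult[s] for controls; variance
    mu + dispersion * mu^2. Returns (counts, per-gene truth table,
    per-sample size multipliers); the multipliers let tests of the GLM use
    the true normalization when the fraction of DE genes is too large for
    median-of-ratios to be unbiased.
    """
    from .diffexpr import CountMatrix  # local import to avoid cycle at import time

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = de_params.n_per_group
    lfc = np.broadcast_to(np.asarray(de_params.true_lfc, float), (n_genes,))
    base = rng.lognormal(de_params.base_mean_log_mu, de_params.base_mean_log_sigma, n_genes)
    mult = rng.uniform(*de_params.size_multiplier_range, size=2 * n)
    mult = mult / np.exp(np.mean(np.log(mult)))  # geometric mean 1
    condition = ["case"] * n + ["control"] * n
    fold = np.where(np.arange(2 * n) < n, 2.0 ** lfc[:, None], 1.0)
    mu = base[:, None] * mult[None, :] * fold
    alpha = float(de_params.dispersion)
    if alpha <= 0:
        raise ValueError("dispersion must be positive")
    size = 1.0 / alpha  # NB number-of-successes parameter
    p = size / (size + mu)
    counts = rng.negative_binomial(size, p)
    gene_ids = [f"GENE{g + 1:04d}" for g in range(n_genes)]
    sample_ids = [f"CASE{i + 1}" for i in range(n)] + [f"CTRL{i + 1}" for i in range(n)]
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        condition=pd.Series(condition, index=sample_ids),
    )
    truth = pd.DataFrame({"gene_id": gene_ids, "true_lfc": lfc, "base_mean": base})
    multipliers = pd.Series(mult, index=sample_ids, name="size_multiplier")
    return cm, truth, multipliers


def simulate_study(
    sim: SimConfig,
    out_dir: str | Path,
    de_n_genes: int | None = None,
    de_lfc: dict[str, float] | None = None,
) -> dict[str, Path]:
    """Discovery + replication + expression inputs for an end-to-end run.

    The replication summary statistics are fresh Z-draws over the *same*
    panel and gene set (independent noise, same per-gene delta), mirroring
    a second cohort of the same population. Counts cover the scan's genes
    with per-gene true log2 fold changes from ``de_lfc`` (default 0).
    """
    out_dir = Path(out_dir)
    disc = simulate_sumstats(sim, out_dir, prefix="discovery")
    panel_mem = disc.pop("_panel_dosages")
    repl_sim = SimConfig(**{**sim.__dict__, "seed": sim.seed + 1_000_003})
    repl = simulate_sumstats(
        repl_sim, out_dir, prefix="replication", panel_dosages=panel_mem, write_panel=False
    )
    repl.pop("_panel_dosages")

    n_de = de_n_genes if de_n_genes is not None else sim.n_genes
    lfc = np.zeros(n_de)
    gene_ids = [f"GENE{g + 1:04d}" for g in range(n_de)]
    if de_lfc:
        for i, gid in enumerate(gene_ids):
            lfc[i] = de_lfc.get(gid, 0.0)
    de_params = DESimParams(
        n_per_group=sim.de.n_per_group,
        true_lfc=lfc,
        dispersion=sim.de.dispersion,
        size_multiplier_range=sim.de.size_multiplier_range,
    )
    cm, de_truth, _ = simulate_counts(de_params, n_de, np.random.default_rng(sim.seed + 7))
    counts_path = out_dir / "counts.tsv"
    cond_path = out_dir / "conditions.tsv"
    cm.to_files(counts_path, cond_path)
    de_truth.to_csv(out_dir / "de.truth.tsv", sep="\t", index=False)

    return {
        "discovery_sumstats": disc["sumstats"],
        "replication_sumstats": repl["sumstats"],
        "genes": disc["genes"],
        "panel": disc["panel"],
        "counts": counts_path,
        "conditions": cond_path,
        "gwas_truth": disc["truth"],
        "de_truth": out_dir / "de.truth.tsv",
    }
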