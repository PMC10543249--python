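"""End-to-end orchestration: discovery scan, replication, DE integration.

Discovery runs the full chain — summary-statistics QC, Z-scores, gene
assignment, panel harmonization, LD estimation and pruning, per-chromosome
bundles, adaptive-test scan with a Bonferroni family-wise threshold.
Replication re-tests only the discovery-significant genes against a second
summary-statistics file at an unadjusted threshold (default 0.05), and the
expression stage contributes per-gene log2 fold changes with BH-adjusted
p-values. The integrated report flags each gene on all three axes; the
overall flag is their conjunction.

Every stage writes its counters into a run manifest so QC losses are
auditable, and all randomness flows from the seed in the configuration,
making reruns byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, gene_model, ld_panel, snpset_tests, sumstats

__all__ = [
    "PipelineConfig",
    "DEFAULT_COLUMN_MAP",
    "build_gene_sets",
    "run_discovery",
    "run_replication",
    "run_de",
    "integrate",
    "run_all",
    "plot_manhattan",
]

DEFAULT_COLUMN_MAP = {
    "rsid": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "odds_ratio": "OR",
    "se": "SE",
    "info": "INFO",
}


class ConfigurationError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All inputs, parameters and thresholds for a full run."""

    discovery_sumstats: Path
    genes: Path
    panel_vcf: Path
    out_dir: Path
    replication_sumstats: Path | None = None
    counts: Path | None = None
    conditions: Path | None = None
    sample_subset: Path | None = None
    column_map: dict = field(default_factory=lambda: dict(DEFAULT_COLUMN_MAP))
    genes_format: str | None = None
    # QC
    info_min: float = 0.9
    info_mode: str = "keep_at_least"
    padding_bp: int = 0
    min_snps: int = 2
    r_max: float = 0.9999
    # tests
    rho_grid: tuple = snpset_tests.DEFAULT_RHO_GRID
    at_method: str = "integration"
    mc_draws: int = 200_000
    seed: int = 0
    # thresholds
    alpha_fw: float = 0.05
    n_tests_override: int | None = None
    replication_alpha: float = 0.05
    de_alpha: float = 0.05
    de_min_total: int = 10
    write_outputs: bool = True

    def __post_init__(self) -> None:
        for name in ("discovery_sumstats", "genes", "panel_vcf", "out_dir",
                     "replication_sumstats", "counts", "conditions", "sample_subset"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))
        for name in ("alpha_fw", "replication_alpha", "de_alpha"):
            a = getattr(self, name)
            if not (0 < a < 1):
                raise ConfigurationError(f"{name} must be in (0, 1), got {a}")

    def validate_paths(self, need: Sequence[str]) -> None:
        for name in need:
            p = getattr(self, name)
            if p is None:
                raise ConfigurationError(f"configuration field '{name}' is required here")
            if not Path(p).exists():
                raise ConfigurationError(f"configuration field '{name}': path not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} did not parse to a mapping")
        if "rho_grid" in raw:
            raw["rho_grid"] = tuple(raw["rho_grid"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(f"bad configuration key: {exc}") from exc


def _read_sample_subset(path: Path | None) -> list[str] | None:
    if path is None:
        return None
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def build_gene_sets(
    sumstats_path: Path,
    config: PipelineConfig,
    manifest: dict,
    stage: str,
    genes: list[gene_model.GeneRegion] | None = None,
    panel: list[ld_panel.PanelVariant] | None = None,
) -> list[ld_panel.GeneSnpSet]:
    """Sumstats → QC → Z → gene assignment → harmonize → LD → prune."""
    counters: dict = {}
    read = sumstats.read_sumstats(sumstats_path, config.column_map)
    counters["parsed"] = len(read.records)
    counters["rejected_rows"] = len(read.rejections)

    records, qc_report = sumstats.qc_filter(
        read.records, info_min=config.info_min, info_mode=config.info_mode
    )
    counters["qc"] = qc_report.as_dict()
    sumstats.compute_z_all(records)

    if genes is None:
        genes = gene_model.load_genes(config.genes, format=config.genes_format)
    counters["genes_loaded"] = len(genes)
    assignments, dropped = gene_model.assign_snps(
        records, genes, padding_bp=config.padding_bp, min_snps=config.min_snps
    )
    counters["genes_assigned"] = len(assignments)
    counters["genes_dropped_min_snps"] = len(dropped)

    if panel is None:
        panel, skipped = ld_panel.load_panel(
            config.panel_vcf, sample_subset=_read_sample_subset(config.sample_subset)
        )
        counters["panel_variants"] = len(panel)
        counters["panel_skipped"] = skipped

    gene_sets: list[ld_panel.GeneSnpSet] = []
    ld_dropped: list[tuple[str, str]] = []
    for assignment in assignments:
        harmonized = ld_panel.harmonize(assignment, panel)
        try:
            gene_sets.append(ld_panel.build_gene_set(harmonized, r_max=config.r_max))
        except ld_panel.EmptyLDError as exc:
            ld_dropped.append((assignment.gene_id, str(exc)))
    counters["genes_tested"] = len(gene_sets)
    counters["genes_dropped_ld"] = len(ld_dropped)
    manifest[stage] = counters
    if ld_dropped:
        manifest[stage]["ld_dropped_detail"] = ld_dropped
    return gene_sets


def run_discovery(config: PipelineConfig) -> snpset_tests.GeneScanResult:
    """Full discovery chain; writes results, Manhattan table and manifest."""
    config.validate_paths(["discovery_sumstats", "genes", "panel_vcf"])
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed}

    gene_sets = build_gene_sets(config.discovery_sumstats, config, manifest, "discovery")
    if not gene_sets:
        raise ValueError("no testable genes after QC/harmonization")
    if config.write_outputs:
        bundle_dir = ld_panel.build_bundles(gene_sets, out / "bundles_discovery")
        manifest["discovery"]["bundle_dir"] = str(bundle_dir)

    scan = snpset_tests.gene_scan(
        gene_sets,
        alpha_fw=config.alpha_fw,
        n_tests=config.n_tests_override,
        rho_grid=config.rho_grid,
        method=config.at_method,
        mc_draws=config.mc_draws,
        seed=config.seed,
    )
    manifest["discovery"]["threshold"] = scan.threshold
    manifest["discovery"]["significant"] = int(scan.results["significant"].sum())
    if config.write_outputs:
        scan.results.to_csv(out / "discovery.results.tsv", sep="\t", index=False, float_format="%.10g")
        scan.manhattan.to_csv(out / "discovery.manhattan.tsv", sep="\t", index=False, float_format="%.10g")
        _merge_manifest(out / "run_manifest.json", manifest)
    return scan


def run_replication(
    discovery: snpset_tests.GeneScanResult, config: PipelineConfig
) -> pd.DataFrame:
    """Adaptive test of discovery-significant genes in the replication data.

    Tested at the unadjusted replication threshold (no multiplicity
    correction; only the discovery-significant genes are re-tested).
    Genes that cannot be re-tested (absent or with < min_snps usable SNPs
    in the replication data) are flagged not-testable.
    """
    config.validate_paths(["replication_sumstats", "genes", "panel_vcf"])
    sig = discovery.results[discovery.results["significant"]]
    if sig.empty:
        raise ValueError("no discovery-significant genes; nothing to replicate")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {}
    gene_sets = build_gene_sets(config.replication_sumstats, config, manifest, "replication")
    by_id = {gs.gene_id: gs for gs in gene_sets}

    rows = []
    for i, gene_id in enumerate(sig["gene_id"]):
        gs = by_id.get(gene_id)
        if gs is None:
            rows.append({"gene_id": gene_id, "p_replication": np.nan,
                         "replicated": False, "testable": False})
            continue
        res = snpset_tests.adaptive_test(
            gs.z, gs.ld.r, rho_grid=config.rho_grid, method=config.at_method,
            mc_draws=config.mc_draws, seed=config.seed + 10_000 + i, gene_id=gene_id,
        )
        rows.append({
            "gene_id": gene_id,
            "p_replication": res.p_at,
            "replicated": bool(res.p_at < config.replication_alpha),
            "testable": True,
        })
    table = pd.DataFrame(rows)
    manifest["replication"]["tested"] = int(table["testable"].sum())
    manifest["replication"]["replicated"] = int(table["replicated"].sum())
    table.to_csv(out / "replication.results.tsv", sep="\t", index=False, float_format="%.10g")
    _merge_manifest(out / "run_manifest.json", manifest)
    return table


def run_de(config: PipelineConfig) -> pd.DataFrame:
    """Expression stage on the configured count matrix."""
    config.validate_paths(["counts", "conditions"])
    cm = diffexpr.CountMatrix.from_files(config.counts, config.conditions)
    table = diffexpr.run_de(cm, min_total=config.de_min_total)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "de.results.tsv", sep="\t", index=False, float_format="%.10g")
    _merge_manifest(out / "run_manifest.json", {"de": {
        "genes_tested": int(table["converged"].sum()),
        "genes_significant": int((table["p_adj"] < config.de_alpha).sum()),
    }})
    return table


def integrate(
    discovery: snpset_tests.GeneScanResult,
    replication: pd.DataFrame | None,
    de_results: pd.DataFrame | None,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Join the three analyses into the final per-gene report.

    One row per discovery-significant gene with its discovery p, the
    replication p and flag, the DE log2 fold change with raw and adjusted
    p, and the overall flag (conjunction of the three). Absent stages
    leave their flag undefined (NA) and the overall flag NA.
    """
    for name, df in (("discovery", discovery.results),):
        if df["gene_id"].duplicated().any():
            raise ValueError(f"duplicate gene ids in {name} input")
    sig = discovery.results[discovery.results["significant"]].copy()
    report = sig[["gene_id", "chrom", "p_at"]].rename(columns={"p_at": "p_discovery"})
    report["discovery_significant"] = True

    if replication is not None:
        if replication["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids in replication input")
        report = report.merge(
            replication[["gene_id", "p_replication", "replicated"]], on="gene_id", how="left"
        )
    else:
        report["p_replication"] = np.nan
        report["replicated"] = pd.NA

    if de_results is not None:
        de = de_results[["gene_id", "lfc", "p", "p_adj"]].rename(
            columns={"p": "p_de", "p_adj": "p_de_adj"}
        )
        if de["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids in DE input")
        report = report.merge(de, on="gene_id", how="left")
        report["de_significant"] = (report["p_de_adj"] < config.de_alpha).astype("boolean")
        report.loc[report["p_de_adj"].isna(), "de_significant"] = pd.NA
    else:
        report["lfc"] = np.nan
        report["p_de"] = np.nan
        report["p_de_adj"] = np.nan
        report["de_significant"] = pd.NA

    def _overall(row) -> object:
        flags = (row["discovery_significant"], row["replicated"], row["de_significant"])
        if any(pd.isna(f) for f in flags):
            return pd.NA
        return bool(all(flags))

    report["all_three"] = report.apply(_overall, axis=1)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_csv(out / "integrated.report.tsv", sep="\t", index=False, float_format="%.10g")
    passing = report[report["all_three"] == True]  # noqa: E712  (NA-aware)
    summary = (
        "genes significant in all three analyses: "
        + (", ".join(passing["gene_id"]) if len(passing) else "none")
        + "\n"
    )
    (out / "integrated.summary.txt").write_text(summary)
    return report


def run_all(config: PipelineConfig) -> pd.DataFrame:
    """Discovery → replication (if configured) → DE (if configured) → report."""
    scan = run_discovery(config)
    replication = None
    if config.replication_sumstats is not None and scan.results["significant"].any():
        replication = run_replication(scan, config)
    de_results = None
    if config.counts is not None:
        de_results = run_de(config)
    return integrate(scan, replication, de_results, config)


def plot_manhattan(manhattan: pd.DataFrame, threshold: float, path: str | Path) -> Path:
    """Manhattan-style plot of per-gene -log10 p against position."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3.5))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, grp) in enumerate(manhattan.groupby("chrom", sort=False)):
        x = grp["midpoint"].to_numpy() + offset
        ax.scatter(x, grp["neg_log10_p"], s=8, color=["#3b5b92", "#8aa0c8"][i % 2])
        ticks.append(x.mean())
        labels.append(str(chrom))
        offset = x.max() + 1
    ax.axhline(-np.log10(threshold), ls="--", color="crimson", lw=1)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}\,p$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def _merge_manifest(path: Path, update: dict) -> None:
    manifest = json.loads(path.read_text()) if path.exists() else {}
    manifest.update(update)
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
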