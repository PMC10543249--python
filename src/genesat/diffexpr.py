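"""Simplified negative-binomial differential expression.

A deliberately minimal two-group analysis in the style of count-based
RNA-seq tools: median-of-ratios size factors, per-gene NB GLM (log link,
intercept + condition, log size factors as offset) with method-of-moments
dispersion, a Wald test on the log2 fold change, and Benjamini-Hochberg
adjustment. No dispersion shrinkage, no outlier handling, no LFC
shrinkage — this is a transparent analog of that analysis class, not a
reimplementation of any particular tool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "DEResult",
    "filter_low_counts",
    "size_factors",
    "nb_wald_test",
    "bh_adjust",
    "fold_change",
    "run_de",
]

_LN2 = np.log(2.0)
_DISPERSION_FLOOR = 1e-8


@dataclass
class CountMatrix:
    """Gene-by-sample integer counts plus per-sample condition labels."""

    counts: pd.DataFrame  # genes x samples
    condition: pd.Series  # sample -> {case, control}

    def __post_init__(self) -> None:
        self.condition = self.condition.reindex(self.counts.columns)
        if self.condition.isna().any():
            missing = list(self.condition[self.condition.isna()].index)
            raise ValueError(f"samples missing a condition label: {missing}")
        bad = set(self.condition.unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"condition labels must be case/control, got {bad}")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integral")
        for lvl in ("case", "control"):
            if (self.condition == lvl).sum() < 1:
                raise ValueError(f"need at least one {lvl} sample")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def to_files(self, counts_path: str | Path, condition_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
        self.condition.rename("condition").to_csv(
            condition_path, sep="\t", index_label="sample_id"
        )

    @classmethod
    def from_files(cls, counts_path: str | Path, condition_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        cond = pd.read_csv(condition_path, sep="\t", index_col=0)["condition"]
        return cls(counts=counts, condition=cond)


@dataclass
class DEResult:
    """Per-gene differential-expression outcome (log2 scale)."""

    gene_id: str
    mean_norm_count: float
    lfc: float
    lfc_se: float
    wald: float
    p: float | None
    p_adj: float | None = None
    converged: bool = True


def filter_low_counts(cm: CountMatrix, min_total: int = 10) -> tuple[CountMatrix, int]:
    """Keep genes whose total count across all samples is >= min_total."""
    totals = cm.counts.sum(axis=1)
    keep = totals >= min_total
    dropped = int((~keep).sum())
    return CountMatrix(counts=cm.counts[keep], condition=cm.condition), dropped


def size_factors(cm: CountMatrix, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-gene geometric mean across samples, taken
    over genes expressed in every sample; each sample's factor is the
    median ratio of its counts to the reference. ``pseudo_reference=True``
    adds a pseudocount of 1 so the reference exists even when no gene is
    expressed everywhere.
    """
    counts = cm.counts.to_numpy(dtype=float)
    if pseudo_reference:
        counts = counts + 1.0
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts)
    all_pos = np.isfinite(log_counts).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene is expressed in every sample; rerun with pseudo_reference=True"
        )
    log_geo = log_counts[all_pos].mean(axis=1)
    ratios = log_counts[all_pos] - log_geo[:, None]
    log_sf = np.median(ratios, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean exactly 1
    return pd.Series(np.exp(log_sf), index=cm.counts.columns, name="size_factor")


def _moment_dispersion(norm_counts: np.ndarray, case: np.ndarray) -> float:
    """Method-of-moments NB dispersion, pooled across the two groups.

    Uses within-group means/variances of normalized counts:
    alpha = (s^2 - mu) / mu^2, averaged over groups weighted by df.
    """
    num = 0.0
    den = 0.0
    for mask in (case, ~case):
        y = norm_counts[mask]
        if y.size < 2:
            continue
        mu = y.mean()
        if mu <= 0:
            continue
        s2 = y.var(ddof=1)
        num += (s2 - mu) / mu**2 * (y.size - 1)
        den += y.size - 1
    if den == 0:
        return _DISPERSION_FLOOR
    return max(num / den, _DISPERSION_FLOOR)


def nb_wald_test(
    cm: CountMatrix,
    factors: pd.Series | Sequence[float] | None = None,
    dispersion_mode: str = "per_gene_moments",
    fixed_dispersion: float = 0.1,
) -> list[DEResult]:
    """Per-gene NB GLM Wald test of case vs control.

    Design: intercept + condition indicator (case = 1), offset = log size
    factors; the natural-log coefficient is converted to log2. Dispersion
    is per-gene method-of-moments (floored at 1e-8) or a fixed value.
    Genes whose fit does not converge are flagged with ``p = None`` and
    excluded from downstream adjustment.
    """
    if dispersion_mode not in ("per_gene_moments", "fixed"):
        raise ValueError(f"unknown dispersion_mode: {dispersion_mode!r}")
    if factors is None:
        factors = size_factors(cm)
    sf = np.asarray(factors, dtype=float)
    case = (cm.condition == "case").to_numpy()
    for mask in (case, ~case):
        if dispersion_mode == "per_gene_moments" and mask.sum() < 2:
            raise ValueError("per-gene dispersion estimation needs >= 2 samples per group")
    design = sm.add_constant(case.astype(float))
    offset = np.log(sf)
    counts = cm.counts.to_numpy(dtype=float)
    norm_counts = counts / sf[None, :]

    results: list[DEResult] = []
    for gi, gene_id in enumerate(cm.counts.index):
        y = counts[gi]
        if dispersion_mode == "fixed":
            alpha = max(fixed_dispersion, _DISPERSION_FLOOR)
        else:
            alpha = _moment_dispersion(norm_counts[gi], case)
        mean_norm = float(norm_counts[gi].mean())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GLM(
                    y, design, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
                )
                fit = model.fit(maxiter=100, tol=1e-8)
            beta = float(fit.params[1])
            se = float(fit.bse[1])
            converged = bool(fit.converged) and np.isfinite(beta) and np.isfinite(se) and se > 0
        except Exception:
            converged = False
        if not converged:
            results.append(
                DEResult(
                    gene_id=str(gene_id), mean_norm_count=mean_norm,
                    lfc=np.nan, lfc_se=np.nan, wald=np.nan, p=None, converged=False,
                )
            )
            continue
        wald = beta / se
        p = float(min(max(2.0 * norm.sf(abs(wald)), 1e-300), 1.0))
        results.append(
            DEResult(
                gene_id=str(gene_id),
                mean_norm_count=mean_norm,
                lfc=beta / _LN2,
                lfc_se=se / _LN2,
                wald=wald,
                p=p,
            )
        )
    return results


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(lfc: float) -> float:
    """Multiplicative fold change 2**lfc from a log2 fold change."""
    return float(2.0**lfc)


def run_de(
    cm: CountMatrix,
    min_total: int = 10,
    dispersion_mode: str = "per_gene_moments",
    fixed_dispersion: float = 0.1,
    pseudo_reference: bool = False,
) -> pd.DataFrame:
    """Filter, normalize, test and adjust; returns a tidy results table.

    Columns: gene_id, mean_norm_count, lfc, lfc_se, wald, p, p_adj,
    fold_change, converged. Non-converged genes carry NaN p/p_adj and are
    excluded from the BH adjustment.
    """
    filtered, _ = filter_low_counts(cm, min_total=min_total)
    sf = size_factors(filtered, pseudo_reference=pseudo_reference)
    res = nb_wald_test(
        filtered, sf, dispersion_mode=dispersion_mode, fixed_dispersion=fixed_dispersion
    )
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in res],
            "mean_norm_count": [r.mean_norm_count for r in res],
            "lfc": [r.lfc for r in res],
            "lfc_se": [r.lfc_se for r in res],
            "wald": [r.wald for r in res],
            "p": [r.p if r.p is not None else np.nan for r in res],
            "converged": [r.converged for r in res],
        }
    )
    df["p_adj"] = np.nan
    ok = df["p"].notna()
    if ok.any():
        df.loc[ok, "p_adj"] = bh_adjust(df.loc[ok, "p"].to_numpy())
    df["fold_change"] = 2.0 ** df["lfc"]
    return df
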