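"""Reading, validation and QC of GWAS summary statistics.

Input is delimited text (tab or whitespace) with one row per variant and a
header line; a column map assigns file columns to the roles the pipeline
needs (rsid, chromosome, position, effect/other allele, odds ratio,
standard error, optional INFO imputation-quality score).

QC mirrors the standard preparation of case-control summary data for
gene-based testing: autosomes only, imputation-quality filter, removal of
strand-ambiguous (A/T, C/G) and non-biallelic sites and of duplicated
rsIDs, then per-variant Z-scores z = ln(OR)/SE oriented to the effect
allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SummaryStatRecord",
    "QCReport",
    "ReadResult",
    "read_sumstats",
    "qc_filter",
    "compute_z",
]

AUTOSOMES = {str(i) for i in range(1, 23)}
VALID_CHROMS = AUTOSOMES | {"X", "Y", "MT"}
AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})

#: roles the column map must cover
REQUIRED_ROLES = ("rsid", "chrom", "pos", "effect_allele", "other_allele", "odds_ratio", "se")


class ConfigurationError(ValueError):
    """A required column role is missing from the column map or file."""


class InputError(ValueError):
    """The input file is empty or structurally unusable."""


def normalize_chrom(label: str) -> str:
    """Map 'chr1'/'1' → '1', 'chrM'/'MT' → 'MT'; case-insensitive."""
    c = str(label).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    c = c.upper()
    if c == "M":
        c = "MT"
    if c.endswith(".0") and c[:-2].isdigit():  # pandas float-parsed chrom
        c = c[:-2]
    return c


@dataclass
class SummaryStatRecord:
    """One GWAS variant: identifiers, alleles, effect estimate, derived Z."""

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    odds_ratio: float
    se: float
    info: float | None = None
    z: float | None = None

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        self.effect_allele = self.effect_allele.upper()
        self.other_allele = self.other_allele.upper()

    @property
    def allele_pair(self) -> frozenset[str]:
        return frozenset((self.effect_allele, self.other_allele))

    def validate(self) -> str | None:
        """Return a reason string if the record is malformed, else None."""
        if not self.rsid:
            return "missing rsid"
        if self.pos < 1:
            return "position < 1"
        if not (self.odds_ratio > 0) or not math.isfinite(self.odds_ratio):
            return "odds ratio not a positive finite number"
        if not (self.se > 0) or not math.isfinite(self.se):
            return "standard error not a positive finite number"
        if self.effect_allele == self.other_allele:
            return "effect and other allele identical"
        if not self.effect_allele or not self.other_allele:
            return "missing allele"
        return None


@dataclass
class QCReport:
    """Per-rule removal tallies, in the order the rules are applied."""

    n_input: int = 0
    removed_non_autosomal: int = 0
    removed_info: int = 0
    removed_ambiguous: int = 0
    removed_non_biallelic: int = 0
    removed_duplicate_rsid: int = 0
    n_output: int = 0

    def reconciles(self) -> bool:
        removed = (
            self.removed_non_autosomal
            + self.removed_info
            + self.removed_ambiguous
            + self.removed_non_biallelic
            + self.removed_duplicate_rsid
        )
        return self.n_input - removed == self.n_output

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "removed_non_autosomal": self.removed_non_autosomal,
            "removed_info": self.removed_info,
            "removed_ambiguous": self.removed_ambiguous,
            "removed_non_biallelic": self.removed_non_biallelic,
            "removed_duplicate_rsid": self.removed_duplicate_rsid,
            "n_output": self.n_output,
        }


@dataclass
class ReadResult:
    """Parsed records plus the rejection report (1-based data row, reason)."""

    records: list[SummaryStatRecord]
    rejections: list[tuple[int, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def write_rejections(self, path: str | Path) -> None:
        pd.DataFrame(self.rejections, columns=["row", "reason"]).to_csv(
            path, sep="\t", index=False
        )


def read_sumstats(path: str | Path, column_map: Mapping[str, str]) -> ReadResult:
    """Parse a summary-statistics file into records.

    Parameters
    ----------
    path:
        Delimited text file with a header row. Tab- or whitespace-delimited.
    column_map:
        Maps each role (``rsid``, ``chrom``, ``pos``, ``effect_allele``,
        ``other_allele``, ``odds_ratio``, ``se``, optionally ``info``) to a
        column name in the file's header.

    Returns
    -------
    ReadResult
        Records for every parseable row; unparseable rows are listed in
        ``rejections`` with their 1-based data-row number and a reason.
    """
    missing_roles = [r for r in REQUIRED_ROLES if r not in column_map]
    if missing_roles:
        raise ConfigurationError(f"column map missing roles: {missing_roles}")

    try:
        df = pd.read_csv(path, sep=r"\s+", dtype=str, comment=None)
    except pd.errors.EmptyDataError:
        raise InputError(f"empty summary-statistics file: {path}") from None
    if df.empty:
        raise InputError(f"summary-statistics file has a header but no rows: {path}")

    missing_cols = [c for c in column_map.values() if c not in df.columns]
    if missing_cols:
        raise ConfigurationError(
            f"mapped columns not present in {path}: {missing_cols} "
            f"(header: {list(df.columns)})"
        )

    has_info = "info" in column_map
    records: list[SummaryStatRecord] = []
    rejections: list[tuple[int, str]] = []
    cols = {role: df[name] for role, name in column_map.items()}
    for i in range(len(df)):
        row = i + 1
        try:
            info_val: float | None = None
            if has_info:
                raw_info = cols["info"].iloc[i]
                if raw_info is not None and str(raw_info).upper() not in ("", "NA", "NAN", "."):
                    info_val = float(raw_info)
            rec = SummaryStatRecord(
                rsid=str(cols["rsid"].iloc[i]).strip(),
                chrom=str(cols["chrom"].iloc[i]),
                pos=int(float(cols["pos"].iloc[i])),
                effect_allele=str(cols["effect_allele"].iloc[i]).strip(),
                other_allele=str(cols["other_allele"].iloc[i]).strip(),
                odds_ratio=float(cols["odds_ratio"].iloc[i]),
                se=float(cols["se"].iloc[i]),
                info=info_val,
            )
        except (TypeError, ValueError) as exc:
            rejections.append((row, f"unparseable field: {exc}"))
            continue
        reason = rec.validate()
        if reason is not None:
            rejections.append((row, reason))
            continue
        records.append(rec)
    return ReadResult(records=records, rejections=rejections)


def _is_ambiguous(rec: SummaryStatRecord) -> bool:
    return rec.allele_pair in AMBIGUOUS_PAIRS


def qc_filter(
    records: Iterable[SummaryStatRecord],
    info_min: float = 0.9,
    info_mode: str = "keep_at_least",
    drop_ambiguous: bool = True,
    autosomes_only: bool = True,
) -> tuple[list[SummaryStatRecord], QCReport]:
    """Apply the QC rules in fixed order and tally removals.

    Order: autosome filter → INFO filter → strand-ambiguous / non-biallelic
    filter → duplicate-rsID filter. ``info_mode='keep_at_least'`` keeps
    variants with INFO ≥ ``info_min`` (standard imputation-quality rule);
    ``'drop_above_literal'`` instead drops variants with INFO > ``info_min``.
    Variants with missing INFO are retained under either mode. Duplicate
    rsIDs remove *every* record sharing the duplicated ID. Non-biallelic
    sites are detected as multiple records at one (chrom, pos) with
    inconsistent allele pairs; all of them are dropped.
    """
    if info_mode not in ("keep_at_least", "drop_above_literal"):
        raise ValueError(f"unknown info_mode: {info_mode!r}")
    recs = list(records)
    report = QCReport(n_input=len(recs))

    if autosomes_only:
        kept = [r for r in recs if r.chrom in AUTOSOMES]
        report.removed_non_autosomal = len(recs) - len(kept)
        recs = kept

    if info_mode == "keep_at_least":
        kept = [r for r in recs if r.info is None or r.info >= info_min]
    else:
        kept = [r for r in recs if r.info is None or not (r.info > info_min)]
    report.removed_info = len(recs) - len(kept)
    recs = kept

    if drop_ambiguous:
        kept = [r for r in recs if not _is_ambiguous(r)]
        report.removed_ambiguous = len(recs) - len(kept)
        recs = kept

    # non-biallelic: >1 allele pair observed at the same site
    pairs_at_site: dict[tuple[str, int], set[frozenset[str]]] = {}
    for r in recs:
        pairs_at_site.setdefault((r.chrom, r.pos), set()).add(r.allele_pair)
    kept = [r for r in recs if len(pairs_at_site[(r.chrom, r.pos)]) == 1]
    report.removed_non_biallelic = len(recs) - len(kept)
    recs = kept

    rsid_counts: dict[str, int] = {}
    for r in recs:
        rsid_counts[r.rsid] = rsid_counts.get(r.rsid, 0) + 1
    kept = [r for r in recs if rsid_counts[r.rsid] == 1]
    report.removed_duplicate_rsid = len(recs) - len(kept)
    recs = kept

    report.n_output = len(recs)
    return recs, report


def compute_z(record: SummaryStatRecord) -> float:
    """Z-score from the odds ratio and its standard error: ln(OR)/SE.

    The sign is oriented to the effect allele; it is stored on the record
    and returned.
    """
    if not (record.odds_ratio > 0):
        raise ValueError(f"odds ratio must be positive, got {record.odds_ratio}")
    if not (record.se > 0):
        raise ValueError(f"standard error must be positive, got {record.se}")
    record.z = math.log(record.odds_ratio) / record.se
    return record.z


def compute_z_all(records: Sequence[SummaryStatRecord]) -> list[SummaryStatRecord]:
    for r in records:
        compute_z(r)
    return list(records)
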