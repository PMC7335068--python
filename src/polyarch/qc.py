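"""Quality control for GWAS summary statistics.

Summary statistics travel as pandas DataFrames with the canonical columns
``SNP, CHR, BP, A1, A2, MAF, BETA, SE, Z, P, N`` (an LDSC-compatible
subset).  The QC pipeline applies, in order:

1. restriction to a reference panel of common SNPs (MAF > 0.05), with
   allele harmonisation (an A1/A2 swap versus the panel flips the sign of
   the effect estimate);
2. removal of SNPs with low effective genotyping coverage: per-SNP sample
   size below 0.67 times the 90th percentile of sample sizes;
3. exclusion of the MHC region (chromosome 6, 26-34 Mb inclusive), whose
   complex long-range LD distorts effect-size-distribution estimation;
4. extraction of extreme large-effect loci: greedy clumping of SNPs with
   chi-square (z^2) above 80, removing everything within 1 Mb of, or in
   squared LD above 0.1 with, each retained top SNP.  The independent top
   SNPs are kept aside and their contribution is added back to totals after
   mixture fitting.

Each filter is idempotent and logs what it drops; `apply_qc` composes all
four and returns the cleaned records, the large-effect set, and a per-SNP
drop report.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MHC_CHROM = 6
MHC_START = 26_000_000
MHC_END = 34_000_000

#: canonical summary-statistic columns
SUMSTAT_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "MAF", "BETA", "SE", "Z", "P", "N"]


@dataclass
class LargeEffectSet:
    """Independent top SNPs (chi-square > threshold) clumped out before fitting.

    ``tops`` holds one row per retained top SNP with its effect estimate
    ``BETA`` (beta_hat) and standard error ``SE`` (tau); ``removed_neighbors``
    lists identifiers of SNPs dropped for being within the clumping window
    of, or in LD with, a top SNP.
    """

    tops: pd.DataFrame
    removed_neighbors: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tops)

    @property
    def add_back(self) -> float:
        """Heritability contribution sum_i max(beta_i^2 - tau_i^2, 0)."""
        if len(self.tops) == 0:
            return 0.0
        terms = self.tops["BETA"].to_numpy() ** 2 - self.tops["SE"].to_numpy() ** 2
        if np.any(terms < 0):
            warnings.warn(
                "large-effect SNP with beta^2 < tau^2; clamping its add-back at 0",
                RuntimeWarning,
            )
            terms = np.maximum(terms, 0.0)
        return float(terms.sum())

    @property
    def betas(self) -> np.ndarray:
        return self.tops["BETA"].to_numpy() if len(self.tops) else np.empty(0)

    @property
    def taus(self) -> np.ndarray:
        return self.tops["SE"].to_numpy() if len(self.tops) else np.empty(0)

    @staticmethod
    def empty() -> "LargeEffectSet":
        return LargeEffectSet(tops=pd.DataFrame(columns=SUMSTAT_COLUMNS))


@dataclass
class QCResult:
    records: pd.DataFrame
    large_effects: LargeEffectSet
    drop_report: pd.DataFrame  # columns: SNP, filter, reason


def _report(snps, filt: str, reason: str) -> pd.DataFrame:
    return pd.DataFrame({"SNP": list(snps), "filter": filt, "reason": reason})


def restrict_to_panel(records: pd.DataFrame, panel) -> pd.DataFrame:
    """Keep records present in the reference panel with panel MAF > 0.05.

    Alleles are harmonised against the panel: a record whose A1/A2 are the
    panel's A2/A1 is kept with BETA (and Z) negated; any other allele
    mismatch drops the record.
    """
    pdf = panel.df if hasattr(panel, "df") else panel
    if len(pdf) == 0:
        raise ValueError("reference panel is empty")
    merged = records.merge(
        pdf[["SNP", "A1", "A2", "MAF"]].rename(
            columns={"A1": "_pA1", "A2": "_pA2", "MAF": "_pMAF"}
        ),
        on="SNP",
        how="inner",
    )
    same = (merged["A1"] == merged["_pA1"]) & (merged["A2"] == merged["_pA2"])
    swapped = (merged["A1"] == merged["_pA2"]) & (merged["A2"] == merged["_pA1"])
    merged = merged[(same | swapped) & (merged["_pMAF"] > 0.05)].copy()
    flip = (merged["A1"] == merged["_pA2"]) & (merged["A2"] == merged["_pA1"])
    merged.loc[flip, "BETA"] = -merged.loc[flip, "BETA"]
    if "Z" in merged.columns:
        merged.loc[flip, "Z"] = -merged.loc[flip, "Z"]
    merged.loc[flip, ["A1", "A2"]] = merged.loc[flip, ["_pA1", "_pA2"]].to_numpy()
    out = merged.drop(columns=["_pA1", "_pA2", "_pMAF"]).reset_index(drop=True)
    logger.info("panel restriction: %d of %d records kept", len(out), len(records))
    return out


def filter_low_sample_size(records: pd.DataFrame, factor: float = 0.67,
                           cutoff: float | None = None) -> pd.DataFrame:
    """Drop records with per-SNP sample size below ``factor`` x Q90(N).

    The 90th percentile uses the nearest-rank convention (the
    ``ceil(0.9 k)``-th order statistic of k sample sizes); the comparison is
    strict, so a record exactly at the cutoff survives.  The rule is
    single-pass: the cutoff comes from the full input distribution.  Pass an
    explicit ``cutoff`` to reuse a previously computed one (re-application
    with the same cutoff is the identity).
    """
    if "N" not in records.columns or records["N"].isna().all():
        warnings.warn("no sample sizes present; sample-size filter is a no-op")
        return records.reset_index(drop=True)
    if cutoff is None:
        n = records["N"].dropna().sort_values().to_numpy()
        q90 = n[math.ceil(0.9 * len(n)) - 1]
        cutoff = factor * q90
    keep = ~(records["N"] < cutoff)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("sample-size filter: dropped %d records below %.1f", dropped, cutoff)
    return records[keep].reset_index(drop=True)


def exclude_mhc(records: pd.DataFrame) -> pd.DataFrame:
    """Drop chromosome-6 records with 26,000,000 <= BP <= 34,000,000 (inclusive)."""
    in_mhc = (
        (records["CHR"] == MHC_CHROM)
        & (records["BP"] >= MHC_START)
        & (records["BP"] <= MHC_END)
    )
    if in_mhc.any():
        logger.info("MHC exclusion: dropped %d records", int(in_mhc.sum()))
    return records[~in_mhc].reset_index(drop=True)


def extract_large_effects(
    records: pd.DataFrame,
    panel=None,
    chi2_threshold: float = 80.0,
    window: int = 1_000_000,
    r2_threshold: float = 0.1,
) -> tuple[LargeEffectSet, pd.DataFrame]:
    """Greedy clumping of extreme-effect loci.

    Repeatedly takes the SNP with the largest remaining z^2 above
    ``chi2_threshold`` as an independent top SNP and removes every SNP on
    the same chromosome within ``window`` bp of it or with squared LD above
    ``r2_threshold`` (LD looked up from ``panel`` when it provides it;
    otherwise position-only).  Ties in z^2 break toward the smaller genomic
    coordinate.  Returns the top SNPs plus the residual records, in which
    every z^2 is at or below the threshold.
    """
    z2 = records["Z"].to_numpy() ** 2
    order = np.lexsort((records["BP"].to_numpy(), records["CHR"].to_numpy(), -z2))
    active = np.ones(len(records), dtype=bool)
    chrom = records["CHR"].to_numpy()
    bp = records["BP"].to_numpy()
    has_ld = panel is not None and getattr(panel, "ld_mode", "independent") != "independent"
    top_idx: list[int] = []
    removed: list[str] = []
    for i in order:
        if not active[i] or z2[i] <= chi2_threshold:
            continue
        top_idx.append(i)
        neighbor = active & (chrom == chrom[i]) & (np.abs(bp - bp[i]) <= window)
        if has_ld:
            r2 = panel.r2_with(records["SNP"].iloc[i], records["SNP"])
            neighbor |= active & (np.asarray(r2) > r2_threshold)
        neighbor[i] = False
        removed.extend(records["SNP"].to_numpy()[neighbor])
        active[neighbor] = False
        active[i] = False
    tops = records.iloc[top_idx].reset_index(drop=True)
    residual = records[active].reset_index(drop=True)
    if top_idx:
        logger.info(
            "large-effect extraction: %d top SNPs, %d neighbors removed",
            len(top_idx),
            len(removed),
        )
    return LargeEffectSet(tops=tops, removed_neighbors=removed), residual


def apply_qc(
    records: pd.DataFrame,
    panel=None,
    chi2_threshold: float = 80.0,
    window: int = 1_000_000,
    r2_threshold: float = 0.1,
    sample_size_factor: float = 0.67,
) -> QCResult:
    """Run the four QC steps in order and return records, tops, and a drop report."""
    reports = []
    n0 = len(records)
    stage = records
    if panel is not None:
        after = restrict_to_panel(stage, panel)
        reports.append(
            _report(set(stage["SNP"]) - set(after["SNP"]), "panel", "absent/mismatched/low-MAF")
        )
        stage = after
    after = filter_low_sample_size(stage, factor=sample_size_factor)
    reports.append(_report(set(stage["SNP"]) - set(after["SNP"]), "sample_size", "N < 0.67*Q90"))
    stage = after
    after = exclude_mhc(stage)
    reports.append(_report(set(stage["SNP"]) - set(after["SNP"]), "mhc", "chr6:26-34Mb"))
    stage = after
    large, residual = extract_large_effects(
        stage, panel, chi2_threshold=chi2_threshold, window=window, r2_threshold=r2_threshold
    )
    reports.append(_report(large.tops["SNP"], "large_effect", "chi2 > threshold (kept aside)"))
    reports.append(_report(large.removed_neighbors, "large_effect", "neighbor of top SNP"))
    drop_report = pd.concat(reports, ignore_index=True)
    # conservation: every input record is accounted for exactly once
    assert n0 == len(residual) + len(drop_report)
    return QCResult(records=residual, large_effects=large, drop_report=drop_report)
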