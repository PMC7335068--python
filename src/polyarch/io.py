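"""Reading and writing summary statistics and life tables.

Summary statistics are tab-delimited text with header columns
``SNP CHR BP A1 A2 MAF BETA SE Z P N`` (an LDSC-sumstats-compatible
subset).  A column-name ``dialect`` map lets files with other headers
(e.g. an ``OR`` column instead of ``BETA``) be ingested; malformed rows
are counted, logged, and skipped.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .qc import SUMSTAT_COLUMNS
from .risk import LifeTables

logger = logging.getLogger(__name__)

_MANDATORY = ["SNP", "CHR", "BP"]


class SumstatsFormatError(ValueError):
    pass


def read_sumstats(path, dialect: dict[str, str] | None = None) -> pd.DataFrame:
    """Read tab-delimited summary statistics into the canonical frame.

    ``dialect`` maps file column names to canonical ones, e.g.
    ``{"rsid": "SNP", "OR": "OR"}``.  If an ``OR`` column is present and
    ``BETA`` is not, ``BETA = log(OR)``.  Missing ``Z`` is derived as
    ``BETA/SE`` and missing ``P`` from ``Z``.  Rows violating the record
    invariants (``SE <= 0``, non-positive position, missing id) are
    skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise SumstatsFormatError(f"{path} contains no records")
    if dialect:
        df = df.rename(columns=dialect)
    if "OR" in df.columns and "BETA" not in df.columns:
        df["BETA"] = np.log(df["OR"])
    missing = [c for c in _MANDATORY if c not in df.columns]
    if "BETA" not in df.columns:
        missing.append("BETA (or OR)")
    if "SE" not in df.columns:
        missing.append("SE")
    if missing:
        raise SumstatsFormatError(f"{path} lacks mandatory columns: {missing}")
    n0 = len(df)
    bad = (
        df["SNP"].isna()
        | df["BETA"].isna()
        | df["SE"].isna()
        | (df["SE"] <= 0)
        | (df["BP"] <= 0)
    )
    if bad.any():
        logger.warning("%s: skipped %d malformed rows", path.name, int(bad.sum()))
        df = df[~bad]
    if df.empty:
        raise SumstatsFormatError(f"{path}: no well-formed records")
    df = df.copy()
    if "Z" not in df.columns:
        df["Z"] = df["BETA"] / df["SE"]
    if "P" not in df.columns:
        df["P"] = 2.0 * stats.norm.sf(np.abs(df["Z"]))
    for col in SUMSTAT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    logger.info("%s: read %d records (%d skipped)", path.name, len(df), n0 - len(df))
    return df[SUMSTAT_COLUMNS].reset_index(drop=True)


def write_sumstats(records: pd.DataFrame, path) -> None:
    records[SUMSTAT_COLUMNS].to_csv(path, sep="\t", index=False)


def write_life_tables(tables: LifeTables, rates_path, weights_path) -> None:
    """Write hazards as CSV (age, incidence, mortality) and weights as CSV."""
    pd.DataFrame({
        "age": tables.ages,
        "incidence": tables.incidence,
        "mortality": tables.mortality,
    }).to_csv(rates_path, index=False)
    tables.weights.to_csv(weights_path, index=False)


def read_life_tables(rates_path, weights_path) -> LifeTables:
    rates = pd.read_csv(rates_path)
    weights = pd.read_csv(weights_path)
    return LifeTables(
        ages=rates["age"].to_numpy(),
        incidence=rates["incidence"].to_numpy(),
        mortality=rates["mortality"].to_numpy(),
        weights=weights[["age_lo", "age_hi", "weight"]],
    )
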