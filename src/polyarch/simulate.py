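"""Synthetic GWAS inputs with the statistical structure the analysis assumes.

Everything downstream of real consortium data is testable against this
module: a HapMap3-like reference panel with optional block-diagonal AR(1)
LD and an MHC-like interval on chromosome 6; true per-SNP effects drawn
from a spike-and-slab normal mixture; summary statistics generated at the
z level (``z_m ~ N(sqrt(n_eff) beta_m, 1)`` under independence, with
LD-weighted means and correlated noise within blocks otherwise); SEER-like
life tables; and a small-scale individual-level cohort for validating the
PRS-variance formula.

The effective-sample-size convention ``n_eff = 4 / (1/n_cases +
1/n_controls)`` is shared between this simulator and the mixture fitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mixture import MixtureModel
from .risk import LifeTables
from .qc import MHC_CHROM, MHC_START, MHC_END, SUMSTAT_COLUMNS

_NUCS = np.array(["A", "C", "G", "T"])


def effective_sample_size(n_cases: int, n_controls: int) -> float:
    """n_eff = 4 / (1/n_cases + 1/n_controls); equals 2*n at a 1:1 ratio."""
    if n_cases < 1 or n_controls < 1:
        raise ValueError("n_cases and n_controls must be at least 1")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


@dataclass
class ReferencePanel:
    """SNP panel with positions, allele frequencies, and block LD structure.

    ``df`` has columns SNP, CHR, BP, A1, A2, MAF, BLOCK.  LD within a block
    is AR(1): ``corr(i, j) = rho^|i - j|`` in block-local SNP order;
    blocks never span chromosomes.  ``ld_mode`` is ``independent`` or
    ``ar1``.
    """

    df: pd.DataFrame = field(repr=False)
    ld_mode: str = "independent"
    rho: float = 0.0

    def __post_init__(self) -> None:
        for chrom, grp in self.df.groupby("CHR"):
            if not grp["BP"].is_monotonic_increasing or grp["BP"].duplicated().any():
                raise ValueError(f"positions not strictly increasing on chr {chrom}")
        if (self.df["MAF"] <= 0.05).any():
            raise ValueError("panel SNPs must have MAF > 0.05")

    def __len__(self) -> int:
        return len(self.df)

    def block_corr(self, size: int) -> np.ndarray:
        """AR(1) correlation matrix for a block of the given size."""
        if self.ld_mode == "independent":
            return np.eye(size)
        idx = np.arange(size)
        return self.rho ** np.abs(idx[:, None] - idx[None, :])

    def r2_with(self, snp: str, others: pd.Series) -> np.ndarray:
        """Squared LD of one SNP with a list of SNP ids (0 across blocks)."""
        pos = self.df.set_index("SNP")
        if snp not in pos.index:
            return np.zeros(len(others))
        blk = pos.loc[snp, "BLOCK"]
        my_rank = int(pos.index.get_loc(snp))
        r2 = np.zeros(len(others))
        if self.ld_mode == "independent":
            return r2
        ranks = pos.index.get_indexer(others)
        same = (ranks >= 0) & (pos["BLOCK"].to_numpy()[ranks] == blk)
        r2[same] = self.rho ** (2 * np.abs(ranks[same] - my_rank))
        return r2

    def ld_scores(self) -> np.ndarray:
        """Per-SNP LD score ell_m = sum_j r^2(m, j) within the block."""
        if self.ld_mode == "independent":
            return np.ones(len(self.df))
        scores = np.empty(len(self.df))
        start = 0
        for _, grp in self.df.groupby("BLOCK", sort=False):
            k = len(grp)
            r2 = self.block_corr(k) ** 2
            scores[start:start + k] = r2.sum(axis=1)
            start += k
        return scores


@dataclass
class TrueArchitecture:
    """True per-SNP effects drawn from a mixture model over a panel."""

    panel: ReferencePanel
    beta: np.ndarray
    causal: np.ndarray
    component: np.ndarray  # 0 = null, 1/2 = causal component index
    model: MixtureModel

    @property
    def h2_realized(self) -> float:
        return float(np.sum(self.beta**2))


@dataclass
class CohortMatrix:
    """Individual-level validation cohort: standardized genotypes + outcome."""

    genotypes: np.ndarray  # individuals x SNPs, mean 0 / variance 1 per SNP
    prs: np.ndarray
    outcome: np.ndarray
    prevalence: float


def make_reference_panel(n_snps: int, n_chromosomes: int = 22,
                         block_size: int = 1, ld_mode: str = "independent",
                         rho: float = 0.0, seed: int = 0) -> ReferencePanel:
    """Deterministic synthetic reference panel.

    SNPs are spread evenly over chromosomes with strictly increasing
    positions; when chromosome 6 is present, a few of its SNPs are placed
    inside the MHC-like interval (26-34 Mb) so the exclusion filter has
    something to act on.  ``ld_mode='ar1'`` groups consecutive SNPs into
    blocks of ``block_size`` with correlation ``rho^|i-j|``.
    """
    if n_snps < 1 or n_chromosomes < 1 or block_size < 1:
        raise ValueError("n_snps, n_chromosomes and block_size must be positive")
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    if ld_mode not in ("independent", "ar1"):
        raise ValueError(f"unknown ld_mode {ld_mode!r}")
    if ld_mode == "independent":
        block_size = 1
    rng = np.random.default_rng(seed)
    per_chrom = np.full(n_chromosomes, n_snps // n_chromosomes)
    per_chrom[: n_snps % n_chromosomes] += 1
    frames = []
    for chrom in range(1, n_chromosomes + 1):
        k = per_chrom[chrom - 1]
        if k == 0:
            continue
        if chrom == MHC_CHROM:
            # guarantee occupancy of the MHC-like interval
            k_mhc = max(1, k // 20)
            pos_mhc = np.sort(rng.integers(MHC_START, MHC_END + 1, size=k_mhc))
            n_rest = k - k_mhc
            lo = rng.integers(1, MHC_START, size=n_rest // 2 + n_rest % 2)
            hi = rng.integers(MHC_END + 1, 120_000_000, size=n_rest // 2)
            pos = np.sort(np.r_[pos_mhc, lo, hi])
        else:
            pos = np.sort(rng.integers(1, 120_000_000, size=k))
        # enforce strict monotonicity after sorting
        pos = pos + np.arange(k)
        a1 = rng.choice(_NUCS, size=k)
        a2_offset = rng.integers(1, 4, size=k)
        a2 = _NUCS[(np.searchsorted(_NUCS, a1) + a2_offset) % 4]
        frames.append(pd.DataFrame({
            "CHR": chrom,
            "BP": pos,
            "A1": a1,
            "A2": a2,
            "MAF": rng.uniform(0.0500001, 0.5, size=k),
        }))
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "SNP", [f"rs{i + 1}" for i in range(len(df))])
    # consecutive blocks within each chromosome
    block_ids = []
    next_block = 0
    for _, grp in df.groupby("CHR", sort=True):
        ids = next_block + np.arange(len(grp)) // block_size
        block_ids.append(ids)
        next_block = ids[-1] + 1
    df["BLOCK"] = np.concatenate(block_ids)
    return ReferencePanel(df=df, ld_mode=ld_mode, rho=rho if ld_mode == "ar1" else 0.0)


def simulate_effect_sizes(panel: ReferencePanel, model: MixtureModel,
                          seed: int = 0) -> TrueArchitecture:
    """Draw i.i.d. per-SNP true effects from the spike-and-slab mixture."""
    rng = np.random.default_rng(seed)
    m = len(panel)
    causal = rng.random(m) < model.pi_c
    beta = np.zeros(m)
    component = np.zeros(m, dtype=int)
    n_causal = int(causal.sum())
    if n_causal:
        comp = rng.choice(len(model.components), size=n_causal, p=model.weights)
        sd = np.sqrt(model.variances[comp])
        beta[causal] = rng.standard_normal(n_causal) * sd
        component[causal] = comp + 1
    return TrueArchitecture(panel=panel, beta=beta, causal=causal,
                            component=component, model=model)


def simulate_summary_stats(arch: TrueArchitecture, n_cases: int, n_controls: int,
                           seed: int = 0, n_jitter: float = 0.0) -> pd.DataFrame:
    """GWAS summary statistics implied by the true architecture.

    Under independence ``z_m ~ N(sqrt(n_eff_m) beta_m, 1)``; within an AR(1)
    LD block the z means are the LD-weighted sums ``R sqrt(n_eff) beta`` and
    the noise is correlated with covariance R.  ``n_jitter`` is the fraction
    of SNPs whose per-SNP sample size is degraded (multiplied by
    U(0.25, 0.9), with z mean and SE scaled consistently), emulating
    variable genotyping coverage; the rest report the exact total.
    """
    if n_jitter < 0 or n_jitter > 1:
        raise ValueError("n_jitter must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    panel = arch.panel
    m = len(panel)
    n_total = n_cases + n_controls
    n_eff = effective_sample_size(n_cases, n_controls)
    u = np.ones(m)
    if n_jitter > 0:
        degraded = rng.random(m) < n_jitter
        u[degraded] = rng.uniform(0.25, 0.9, size=int(degraded.sum()))
    sqrt_n = np.sqrt(n_eff * u)
    signal = sqrt_n * arch.beta
    if panel.ld_mode == "independent":
        z = signal + rng.standard_normal(m)
    else:
        z = np.empty(m)
        chol_cache: dict[int, np.ndarray] = {}
        start = 0
        for _, grp in panel.df.groupby("BLOCK", sort=False):
            k = len(grp)
            r = panel.block_corr(k)
            if k not in chol_cache:
                chol_cache[k] = np.linalg.cholesky(r)
            mean = r @ signal[start:start + k]
            z[start:start + k] = mean + chol_cache[k] @ rng.standard_normal(k)
            start += k
    se = 1.0 / sqrt_n
    out = panel.df[["SNP", "CHR", "BP", "A1", "A2", "MAF"]].copy()
    out["BETA"] = z * se
    out["SE"] = se
    out["Z"] = z
    out["P"] = 2.0 * stats.norm.sf(np.abs(z))
    out["N"] = np.rint(n_total * u).astype(int)
    return out[SUMSTAT_COLUMNS]


def simulate_cohort(arch: TrueArchitecture, n_individuals: int,
                    prevalence: float = 0.1, seed: int = 0) -> CohortMatrix:
    """Small-scale individual-level cohort for validating PRS formulas.

    Standardized genotypes are independent normals (mean 0, variance 1 per
    SNP); the outcome follows a logistic model with intercept chosen so the
    expected prevalence matches ``prevalence`` at PRS = 0.  Intended for
    panels of at most a few thousand SNPs.
    """
    if len(arch.panel) > 5000:
        raise ValueError("cohort simulation is a small-scale mode (M <= 5000)")
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n_individuals, len(arch.panel)))
    prs = g @ arch.beta
    intercept = np.log(prevalence / (1.0 - prevalence))
    p = 1.0 / (1.0 + np.exp(-(intercept + prs)))
    y = (rng.random(n_individuals) < p).astype(int)
    return CohortMatrix(genotypes=g, prs=prs, outcome=y, prevalence=prevalence)


def make_life_tables(peak_incidence: float = 0.005, shape: str = "increasing",
                     mortality_level: float = 0.01, seed: int = 0,
                     age_lo: int = 30, age_hi: int = 80) -> LifeTables:
    """SEER-like synthetic life tables on an annual age grid.

    ``shape='flat'`` gives constant incidence at ``peak_incidence``;
    ``'increasing'`` ramps quadratically from near zero to the peak at the
    oldest age, the typical shape of cancer incidence.  Mortality is flat
    at ``mortality_level``.  Baseline-age weights cover 5-year categories
    from ``age_lo`` to 75, mildly decreasing with age like a census age
    distribution.
    """
    if not 0.0 <= peak_incidence <= 0.5 or not 0.0 <= mortality_level <= 0.5:
        raise ValueError("hazards must lie in [0, 0.5]")
    if shape not in ("flat", "increasing"):
        raise ValueError(f"unknown shape {shape!r}")
    rng = np.random.default_rng(seed)
    ages = np.arange(age_lo, age_hi + 1)
    if shape == "flat":
        incidence = np.full(len(ages), peak_incidence)
    else:
        t = (ages - age_lo) / (age_hi - age_lo)
        incidence = peak_incidence * (0.02 + 0.98 * t**2)
    mortality = np.full(len(ages), mortality_level)
    lows = np.arange(age_lo, 75, 5)
    raw = np.linspace(1.0, 0.6, len(lows)) * rng.uniform(0.95, 1.05, len(lows))
    weights = pd.DataFrame({
        "age_lo": lows,
        "age_hi": lows + 4,
        "weight": raw / raw.sum(),
    })
    return LifeTables(ages=ages, incidence=incidence, mortality=mortality,
                      weights=weights)
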