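"""Projections of future-GWAS yield from a fitted effect-size distribution.

Given mixture parameters (M, pi_c, component weights/variances) and the
set-aside large-effect loci, these routines compute, for a hypothetical
GWAS of effective sample size n and significance threshold alpha:

* ``power``: per-SNP two-sided detection probability
  ``pow(beta) = 1 - Phi(c - sqrt(n) beta) + Phi(-c - sqrt(n) beta)`` with
  ``c = Phi^-1(1 - alpha/2)``;
* ``ED``: expected number of discoveries,
  ``M pi_c E[pow(beta)] + sum_i pow(beta_i)`` with the expectation over the
  causal mixture and the sum over the large-effect loci;
* ``EV``: expected genetic variance explained by the discoveries,
  ``M pi_c E[beta^2 pow(beta)] + sum_i (beta_i^2 - tau_i^2) pow(beta_i)``;
* ``h2_PRS``: the variance of the polygenic score buildable from SNPs
  selected at alpha, ``A^2 / (A + S/n)`` where A is the absolute EV and S
  the expected number of selected SNPs (true discoveries plus
  ``M (1 - pi_c) alpha`` null pass-throughs) — estimation noise in the
  selected coefficients shrinks the usable signal;
* the alpha maximising ``h2_PRS`` (optimized threshold), and the sample
  size at which the explained fraction of h2 reaches a target.

Mixture expectations are evaluated by adaptive quadrature with
component-wise standardisation (beta = sigma_h x, x standard normal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

from .mixture import MixtureModel
from .qc import LargeEffectSet
from . import risk as _risk

GWS_ALPHA = 5e-8
_QUAD_OPTS = dict(epsabs=1e-13, epsrel=1e-10, limit=200)


@dataclass
class ProjectionPoint:
    """Projected yield of a GWAS at one (n_eff, alpha) grid point."""

    n_eff: float
    alpha: float
    ed: float
    ev_abs: float
    ev_frac: float
    h2_prs: float
    threshold_mode: str = "gws"

    @property
    def auc(self) -> float:
        return _risk.auc_from_h2(self.h2_prs)

    @property
    def rr99(self) -> float:
        return _risk.rr_top_percentile(self.h2_prs, 0.99)


def power(beta, n_eff: float, alpha: float):
    """Two-sided detection probability of a standardized log-OR of size beta."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    if n_eff <= 0:
        raise ValueError("n_eff must be positive")
    c = -special.ndtri(alpha / 2.0)  # c_{alpha/2} = Phi^-1(1 - alpha/2)
    shift = np.sqrt(n_eff) * np.asarray(beta, dtype=float)
    # 1 - Phi(c - shift) = Phi(shift - c)
    out = special.ndtr(shift - c) + special.ndtr(-c - shift)
    return float(out) if np.isscalar(beta) else out


def _expect_over_component(n_eff: float, alpha: float, sigma2: float,
                           weight_x2: bool) -> float:
    """E[g(beta) pow(beta)] for beta ~ N(0, sigma2), g = 1 or beta^2/sigma2.

    Standardised as beta = sigma x; integrates x (optionally x^2) times
    pow(sigma x) against the standard normal density.
    """
    sigma = np.sqrt(sigma2)
    c = -special.ndtri(alpha / 2.0)
    sqn = np.sqrt(n_eff) * sigma
    norm_const = 1.0 / np.sqrt(2.0 * np.pi)

    def integrand(x: float) -> float:
        pw = special.ndtr(sqn * x - c) + special.ndtr(-c - sqn * x)
        val = pw * norm_const * np.exp(-0.5 * x * x)
        return x * x * val if weight_x2 else val

    total = 0.0
    for lo, hi in ((-np.inf, 0.0), (0.0, np.inf)):
        val, _ = integrate.quad(integrand, lo, hi, **_QUAD_OPTS)
        total += val
    return total


def _large_powers(large: LargeEffectSet | None, n_eff: float, alpha: float):
    if large is None or len(large) == 0:
        return np.empty(0), np.empty(0)
    pw = power(large.betas, n_eff, alpha)
    terms = np.maximum(large.betas**2 - large.taus**2, 0.0)
    return pw, terms


def expected_discoveries(model: MixtureModel, large: LargeEffectSet | None,
                         n_eff: float, alpha: float) -> float:
    """Expected number of genome-wide discoveries at threshold alpha."""
    mix = sum(
        p_h * _expect_over_component(n_eff, alpha, s2_h, weight_x2=False)
        for p_h, s2_h in model.components
    )
    pw, _ = _large_powers(large, n_eff, alpha)
    return model.M * model.pi_c * mix + float(pw.sum())


def expected_variance(model: MixtureModel, large: LargeEffectSet | None,
                      n_eff: float, alpha: float) -> float:
    """Expected genetic variance (log-OR scale) explained by discoveries."""
    mix = sum(
        p_h * s2_h * _expect_over_component(n_eff, alpha, s2_h, weight_x2=True)
        for p_h, s2_h in model.components
    )
    pw, terms = _large_powers(large, n_eff, alpha)
    return model.M * model.pi_c * mix + float((terms * pw).sum())


def total_h2(model: MixtureModel, large: LargeEffectSet | None) -> float:
    """Heritability ceiling h2 including the large-effect add-back."""
    return model.h2 + (large.add_back if large is not None else 0.0)


def prs_variance(model: MixtureModel, large: LargeEffectSet | None,
                 n_eff: float, alpha: float) -> float:
    """Projected variance of the PRS built from SNPs selected at alpha.

    ``h2_PRS = A^2 / (A + S / n_eff)`` with A the absolute expected variance
    of the selected SNPs and S their expected count including
    ``M (1 - pi_c) alpha`` false-positive null SNPs, whose estimated
    coefficients contribute pure noise of variance 1/n_eff each.
    """
    a = expected_variance(model, large, n_eff, alpha)
    if a <= 0.0:
        return 0.0
    s = expected_discoveries(model, large, n_eff, alpha)
    s += model.M * (1.0 - model.pi_c) * alpha
    return a * a / (a + s / n_eff)


def default_alpha_grid(n_points: int = 61) -> np.ndarray:
    """Log-uniform threshold grid on [1e-12, 0.5], always containing 5e-8."""
    grid = np.logspace(-12, np.log10(0.5), n_points)
    return np.unique(np.append(grid, GWS_ALPHA))


def optimize_threshold(model: MixtureModel, large: LargeEffectSet | None,
                       n_eff: float, alpha_grid: np.ndarray | None = None
                       ) -> tuple[float, float]:
    """Significance threshold maximising the projected PRS variance.

    Returns ``(alpha_star, h2_prs_star)``.  The grid always contains the
    genome-wide threshold, so the optimum is never worse than 5e-8.
    """
    grid = default_alpha_grid() if alpha_grid is None else np.asarray(alpha_grid)
    vals = np.array([prs_variance(model, large, n_eff, a) for a in grid])
    i = int(np.argmax(vals))
    return float(grid[i]), float(vals[i])


def project_point(model: MixtureModel, large: LargeEffectSet | None,
                  n_eff: float, alpha: float | None = None,
                  threshold_mode: str = "gws") -> ProjectionPoint:
    """Full projection at one sample size, at the GWS or optimized threshold."""
    if threshold_mode == "optimized":
        alpha, h2_prs = optimize_threshold(model, large, n_eff)
    else:
        alpha = GWS_ALPHA if alpha is None else alpha
        h2_prs = prs_variance(model, large, n_eff, alpha)
    ed = expected_discoveries(model, large, n_eff, alpha)
    ev = expected_variance(model, large, n_eff, alpha)
    h2 = total_h2(model, large)
    return ProjectionPoint(
        n_eff=n_eff, alpha=alpha, ed=ed, ev_abs=ev,
        ev_frac=ev / h2 if h2 > 0 else np.nan,
        h2_prs=h2_prs, threshold_mode=threshold_mode,
    )


def sample_size_for_fraction(model: MixtureModel, large: LargeEffectSet | None,
                             fraction: float, threshold_mode: str = "optimized",
                             alpha: float = GWS_ALPHA, n_cap: float = 1e8,
                             rel_tol: float = 1e-3) -> float:
    """Smallest n_eff at which the explained fraction of h2 reaches ``fraction``.

    The explained fraction is EV/h2 at the optimized threshold (or at the
    fixed ``alpha`` in ``gws`` mode).  Search doubles n_eff from 1,000 until
    the target is bracketed, then bisects.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    h2 = total_h2(model, large)
    if h2 <= 0:
        raise ValueError("model has no heritability to explain")

    def frac_at(n: float) -> float:
        a = optimize_threshold(model, large, n)[0] if threshold_mode == "optimized" else alpha
        return expected_variance(model, large, n, a) / h2

    lo, hi = 1e3, 1e3
    while frac_at(hi) < fraction:
        lo, hi = hi, hi * 2.0
        if hi > n_cap:
            raise RuntimeError(
                f"fraction {fraction} not reachable below n_eff = {n_cap:.0e}"
            )
    if lo == hi:  # already satisfied at the starting point
        return lo
    while (hi - lo) / hi > rel_tol:
        mid = 0.5 * (lo + hi)
        if frac_at(mid) >= fraction:
            hi = mid
        else:
            lo = mid
    return hi


def projection_curve(model: MixtureModel, large: LargeEffectSet | None,
                     n_eff_grid, threshold_modes=("gws", "optimized")
                     ) -> pd.DataFrame:
    """Projection table over a sample-size grid (Fig. 2-4 style output).

    One row per (n_eff, threshold mode) with expected discoveries, variance
    explained (absolute and as a fraction of h2), projected PRS variance,
    and the implied AUC and relative risk at the 99th percentile.  Case
    counts assume a 1:1 case-control ratio (n_cases = n_eff / 2).
    """
    rows = []
    for n_eff in np.asarray(n_eff_grid, dtype=float):
        for mode in threshold_modes:
            pt = project_point(model, large, n_eff, threshold_mode=mode)
            rows.append({
                "n_eff": n_eff,
                "n_cases": n_eff / 2.0,
                "alpha_mode": mode,
                "alpha": pt.alpha,
                "ED": pt.ed,
                "EV_abs": pt.ev_abs,
                "EV_frac": pt.ev_frac,
                "h2_prs": pt.h2_prs,
                "AUC": pt.auc,
                "RR99": pt.rr99,
            })
    return pd.DataFrame(rows)
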