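"""Normal-mixture effect-size distributions fitted to GWAS z-statistics.

The per-SNP standardized log-odds-ratio beta_m is modelled as a spike-and-
slab mixture: with probability ``1 - pi_c`` the SNP is null (beta = 0),
and with probability ``pi_c`` it is causal with beta drawn from one normal
component (the "two-component" model, counting the null spike) or from a
mixture of two normals with distinct variances (the "three-component"
model, which accommodates a minority of SNPs with much larger effects).

Under an independence (composite-likelihood) approximation the observed
z-statistic of SNP m in a GWAS of effective sample size n marginalises to

    z_m ~ (1 - pi_c) N(0, 1) + pi_c * sum_h p_h N(0, 1 + n sigma_h^2),

optionally inflated per-SNP by an LD score ell_m (``1 + ell_m n sigma_h^2``).
Maximum likelihood on this marginal yields the polygenicity ``M pi_c`` and
the GWAS heritability ``h2 = M pi_c E(beta^2)``, with standard errors from
the inverse observed information and the delta method.  Extreme loci that
were clumped out before fitting are added back to the totals as
``sum_i (beta_i^2 - tau_i^2)``.

Usage follows statsmodels::

    model = EffectSizeMixture(z, n_eff=1e5, M=2e5, n_components=2)
    res = model.fit()
    print(res.summary())
    est = res.heritability(large_effects)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_fprime, approx_hess

from .qc import LargeEffectSet

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    """Raised when no optimizer restart converged; carries the best fit so far."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


@dataclass
class MixtureModel:
    """Parameters of the spike-and-slab effect-size distribution.

    Parameters
    ----------
    M : int
        Number of SNPs on the reference panel.
    pi_c : float
        Fraction of SNPs with non-null effects.
    components : list of (weight, variance)
        Causal-effect normal components, variances ascending; weights sum
        to 1.  One entry for the two-component model, two for the
        three-component model.
    """

    M: int
    pi_c: float
    components: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi_c <= 1.0:
            raise ValueError(f"pi_c must lie in [0, 1], got {self.pi_c}")
        w = np.array([c[0] for c in self.components], dtype=float)
        v = np.array([c[1] for c in self.components], dtype=float)
        if np.any(w < 0) or np.any(w > 1) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("component weights must lie in [0,1] and sum to 1")
        if np.any(v <= 0):
            raise ValueError("component variances must be strictly positive")
        order = np.argsort(v)
        self.components = [(float(w[i]), float(v[i])) for i in order]

    @property
    def n_components(self) -> int:
        """Model order counting the null spike: 2 or 3."""
        return len(self.components) + 1

    @property
    def weights(self) -> np.ndarray:
        return np.array([c[0] for c in self.components])

    @property
    def variances(self) -> np.ndarray:
        return np.array([c[1] for c in self.components])

    @property
    def e_beta2(self) -> float:
        """Mean squared effect among causal SNPs, sum_h p_h sigma_h^2."""
        return float(np.dot(self.weights, self.variances))

    @property
    def h2(self) -> float:
        """Mixture-part GWAS heritability M pi_c E(beta^2)."""
        return self.M * self.pi_c * self.e_beta2

    @property
    def n_susceptibility(self) -> float:
        """Expected number of non-null SNPs, M pi_c."""
        return self.M * self.pi_c

    @property
    def upsilon(self) -> float:
        """Share of heritability carried by the larger-variance component.

        ``p2 sigma_2^2 / (p1 sigma_1^2 + p2 sigma_2^2)``; 0 for the
        single-causal-component model.
        """
        if len(self.components) < 2:
            return 0.0
        p1, s1 = self.components[0]
        p2, s2 = self.components[1]
        return float(p2 * s2 / (p1 * s1 + p2 * s2))


@dataclass
class HeritabilityEstimate:
    """Heritability and polygenicity with large-effect add-back.

    ``h2`` includes the add-back; ``h2_mixture`` is the fitted-mixture part
    alone.  ``per_snp_h2`` is the average heritability per susceptibility
    SNP excluding the extreme loci, (h2 - add_back) / (M pi_c).
    """

    h2: float
    h2_se: float
    n_susceptibility: float
    n_susceptibility_se: float
    upsilon: float
    add_back: float
    n_large: int
    h2_mixture: float

    @property
    def per_snp_h2(self) -> float:
        mix_snps = self.n_susceptibility - self.n_large
        return (self.h2 - self.add_back) / mix_snps if mix_snps > 0 else np.nan


# ---------------------------------------------------------------------------
# marginal likelihood


def _component_logpdfs(z: np.ndarray, variances: np.ndarray) -> np.ndarray:
    # rows: components; variances may be per-SNP (2-D) or scalar per component
    z2 = z**2
    return -0.5 * (np.log(variances) + z2 / variances) - _LOG_SQRT_2PI


def marginal_z_loglik(
    model: MixtureModel,
    z: np.ndarray | pd.DataFrame,
    n_eff: float,
    ld_scores: np.ndarray | None = None,
) -> float:
    """Composite log-likelihood of observed z-statistics under the mixture.

    ``ld_scores`` switches on the LD-score mode, in which the causal
    component variance ``1 + n sigma_h^2`` becomes ``1 + ell_m n sigma_h^2``
    per SNP.
    """
    z = _as_z(z)
    ell = 1.0 if ld_scores is None else np.asarray(ld_scores, dtype=float)
    logps = [np.log1p(-model.pi_c) + _component_logpdfs(z, np.asarray(1.0))]
    if model.pi_c > 0:
        for p_h, s2_h in model.components:
            if p_h == 0:
                continue
            v = 1.0 + ell * n_eff * s2_h
            logps.append(np.log(model.pi_c * p_h) + _component_logpdfs(z, v))
    ll = float(special.logsumexp(np.vstack(logps), axis=0).sum())
    if not np.isfinite(ll):
        raise FloatingPointError(
            f"non-finite marginal log-likelihood at pi_c={model.pi_c}, "
            f"variances={model.variances}"
        )
    return ll


def _as_z(records) -> np.ndarray:
    if isinstance(records, pd.DataFrame):
        return records["Z"].to_numpy(dtype=float)
    return np.asarray(records, dtype=float)


# ---------------------------------------------------------------------------
# transformed parameterisation (unconstrained optimisation scale)
#
# 2-component: theta = [logit(pi_c), log(sigma^2)]
# 3-component: theta = [logit(pi_c), logit(p2), log(s1^2), log(s2^2 - s1^2)]


def _theta_to_model(theta: np.ndarray, M: int, n_components: int) -> MixtureModel:
    pi_c = float(special.expit(theta[0]))
    if n_components == 2:
        return MixtureModel(M=M, pi_c=pi_c, components=[(1.0, float(np.exp(theta[1])))])
    p2 = float(special.expit(theta[1]))
    s1 = float(np.exp(theta[2]))
    s2 = s1 + float(np.exp(theta[3]))
    return MixtureModel(M=M, pi_c=pi_c, components=[(1.0 - p2, s1), (p2, s2)])


def _model_to_theta(model: MixtureModel) -> np.ndarray:
    if model.n_components == 2:
        return np.array([special.logit(model.pi_c), np.log(model.variances[0])])
    (p1, s1), (p2, s2) = model.components
    return np.array(
        [special.logit(model.pi_c), special.logit(p2), np.log(s1), np.log(s2 - s1)]
    )


class EffectSizeMixture:
    """Spike-and-slab mixture model for GWAS z-statistics.

    Parameters
    ----------
    z : array or DataFrame
        Observed z-statistics of cleaned summary statistics (extreme loci
        with chi-square > 80 already extracted), or a summary-statistic
        DataFrame with a ``Z`` column.
    n_eff : float
        Effective sample size of the GWAS, 4 / (1/n_cases + 1/n_controls).
    M : int, optional
        Reference-panel SNP count used in h2 = M pi_c E(beta^2); defaults
        to the number of observations.
    n_components : {2, 3}
        Model order counting the null spike.
    ld_scores : array, optional
        Per-SNP LD scores; switches the marginal variance from
        ``1 + n sigma^2`` to ``1 + ell_m n sigma^2``.
    """

    def __init__(self, z, n_eff: float, M: int | None = None,
                 n_components: int = 2, ld_scores=None):
        self.z = _as_z(z)
        if n_eff <= 0:
            raise ValueError("n_eff must be positive")
        if n_components not in (2, 3):
            raise ValueError("n_components must be 2 or 3")
        self.n_eff = float(n_eff)
        self.M = int(M) if M is not None else len(self.z)
        self.n_components = n_components
        self.ld_scores = None if ld_scores is None else np.asarray(ld_scores, float)
        self.nobs = len(self.z)
        self._z2 = self.z**2
        self._null_logpdf = -0.5 * self._z2 - _LOG_SQRT_2PI

    @classmethod
    def from_dataframe(cls, records: pd.DataFrame, n_eff: float | None = None,
                       **kwargs) -> "EffectSizeMixture":
        """Build from a summary-statistic DataFrame; n_eff defaults to median N."""
        if n_eff is None:
            if "N" not in records.columns:
                raise ValueError("n_eff not given and records carry no N column")
            n_eff = float(records["N"].median())
        return cls(records, n_eff=n_eff, **kwargs)

    # -- likelihood ---------------------------------------------------------

    def loglike(self, params: np.ndarray) -> float:
        """Log-likelihood at a transformed parameter vector.

        Fast path over cached z^2; agrees with :func:`marginal_z_loglik`
        evaluated at the corresponding natural-scale model.
        """
        theta = np.asarray(params, dtype=float)
        pi_c = special.expit(theta[0])
        if self.n_components == 2:
            wv = [(1.0, np.exp(theta[1]))]
        else:
            p2 = special.expit(theta[1])
            s1 = np.exp(theta[2])
            wv = [(1.0 - p2, s1), (p2, s1 + np.exp(theta[3]))]
        ell = 1.0 if self.ld_scores is None else self.ld_scores
        acc = np.log1p(-pi_c) + self._null_logpdf
        for p_h, s2_h in wv:
            if p_h <= 0 or pi_c <= 0:
                continue
            v = 1.0 + ell * self.n_eff * s2_h
            comp = np.log(pi_c * p_h) - 0.5 * (np.log(v) + self._z2 / v) - _LOG_SQRT_2PI
            acc = np.logaddexp(acc, comp)
        ll = float(acc.sum())
        if not np.isfinite(ll):
            raise FloatingPointError(f"non-finite log-likelihood at theta={theta}")
        return ll

    def loglike_model(self, model: MixtureModel) -> float:
        return marginal_z_loglik(model, self.z, self.n_eff, self.ld_scores)

    # -- initialisation grid ------------------------------------------------

    def _moment_sigma2(self, pi_c: float) -> float:
        # E z^2 = 1 + pi_c n E(beta^2) under independence
        excess = max(float(np.mean(self.z**2)) - 1.0, 1e-12)
        return excess / (pi_c * self.n_eff)

    def _default_grid(self) -> list[np.ndarray]:
        grid = []
        for pi_c in (1e-4, 1e-3, 1e-2):
            s2 = self._moment_sigma2(pi_c)
            if self.n_components == 2:
                grid.append(np.array([special.logit(pi_c), np.log(s2)]))
            else:
                for p2, lo, hi in ((0.05, 0.5, 10.0), (0.2, 0.3, 3.0)):
                    grid.append(np.array([
                        special.logit(pi_c), special.logit(p2),
                        np.log(lo * s2), np.log(hi * s2),
                    ]))
        return grid

    # -- fitting ------------------------------------------------------------

    def fit(self, init_grid=None, seed: int = 0, maxiter: int = 4000) -> "MixtureResults":
        """Maximise the marginal likelihood over an initialisation grid.

        For the three-component model the grid is augmented with the fitted
        two-component solution embedded at the boundary (equal component
        variances), which guarantees the nesting property
        loglik(3) >= loglik(2) up to optimizer tolerance.
        """
        del seed  # optimisation is deterministic; kept for interface stability
        grid = list(init_grid) if init_grid is not None else self._default_grid()
        if self.n_components == 3:
            sub = EffectSizeMixture(self.z, self.n_eff, M=self.M,
                                    n_components=2, ld_scores=self.ld_scores)
            res2 = sub.fit(maxiter=maxiter)
            th2 = res2.params
            s2_hat = np.exp(th2[1])
            # s2^2 = s1^2 + 1e-10*s1^2: numerically the 2-component optimum
            grid.append(np.array([th2[0], 0.0, th2[1], np.log(1e-10 * s2_hat)]))
        best = None
        n_converged = 0
        for theta0 in grid:
            res = optimize.minimize(
                lambda t: -self.loglike(t), theta0, method="Nelder-Mead",
                options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-6},
            )
            n_converged += bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        results = MixtureResults(self, best.x, llf=-best.fun,
                                 converged=bool(best.success),
                                 n_restarts=len(grid), n_converged=n_converged)
        if n_converged == 0:
            raise ConvergenceError(
                "no optimizer restart converged within maxiter", best=results
            )
        return results


class MixtureResults:
    """Fit results: parameter estimates, their covariance, and projections.

    ``params`` is the transformed (unconstrained) parameter vector;
    ``mixture`` the fitted :class:`MixtureModel` on the natural scale.
    Standard errors of derived quantities (pi_c, h2, M pi_c) come from the
    delta method applied to the inverse observed information.
    """

    def __init__(self, model: EffectSizeMixture, params: np.ndarray, llf: float,
                 converged: bool, n_restarts: int = 1, n_converged: int = 1):
        self.model = model
        self.params = np.asarray(params, float)
        self.llf = float(llf)
        self.converged = converged
        self.n_restarts = n_restarts
        self.n_converged = n_converged
        self.mixture = _theta_to_model(self.params, model.M, model.n_components)
        self._cov = None

    @property
    def df_model(self) -> int:
        return len(self.params)

    @property
    def bic(self) -> float:
        """Bayesian information criterion with the SNP count as sample size."""
        return self.df_model * np.log(self.model.nobs) - 2.0 * self.llf

    @property
    def aic(self) -> float:
        return 2.0 * self.df_model - 2.0 * self.llf

    def cov_params(self) -> np.ndarray:
        """Inverse observed information on the transformed scale."""
        if self._cov is None:
            hess = approx_hess(self.params, self.model.loglike)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    cov = np.linalg.inv(-hess)
                except np.linalg.LinAlgError:
                    cov = np.linalg.pinv(-hess)
            if np.any(np.diag(cov) < 0):
                warnings.warn(
                    "observed information not positive definite; "
                    "standard errors may be unreliable", RuntimeWarning,
                )
                cov = np.abs(cov)
            self._cov = cov
        return self._cov

    def _delta_se(self, func) -> float:
        """Delta-method SE of a scalar function of the transformed params."""
        grad = approx_fprime(self.params, lambda t: np.atleast_1d(func(t)),
                             centered=True).ravel()
        var = float(grad @ self.cov_params() @ grad)
        return float(np.sqrt(max(var, 0.0)))

    def _derived(self, name: str):
        M, k = self.model.M, self.model.n_components
        return lambda t: getattr(_theta_to_model(t, M, k), name)

    @property
    def pi_c(self) -> float:
        return self.mixture.pi_c

    @property
    def pi_c_se(self) -> float:
        return self._delta_se(self._derived("pi_c"))

    @property
    def h2(self) -> float:
        """Mixture-part heritability (without large-effect add-back)."""
        return self.mixture.h2

    @property
    def h2_se(self) -> float:
        return self._delta_se(self._derived("h2"))

    @property
    def n_susceptibility_se(self) -> float:
        return self._delta_se(self._derived("n_susceptibility"))

    @property
    def upsilon_se(self) -> float:
        return self._delta_se(self._derived("upsilon"))

    def heritability(self, large_effects: LargeEffectSet | None = None) -> HeritabilityEstimate:
        """Total heritability and polygenicity including large-effect add-back."""
        return total_heritability(self.mixture, large_effects, results=self)

    def summary(self, large_effects: LargeEffectSet | None = None) -> str:
        est = self.heritability(large_effects)
        mix = self.mixture
        lines = [
            "Effect-size mixture model (maximum likelihood)",
            "=" * 58,
            f"components (incl. null spike): {mix.n_components}",
            f"SNPs in likelihood:            {self.model.nobs}",
            f"panel size M:                  {mix.M}",
            f"effective sample size:         {self.model.n_eff:.0f}",
            f"log-likelihood:                {self.llf:.3f}",
            f"BIC:                           {self.bic:.3f}",
            f"converged:                     {self.converged}"
            f" ({self.n_converged}/{self.n_restarts} restarts)",
            "-" * 58,
            f"pi_c:                 {mix.pi_c:.4e} (SE {self.pi_c_se:.2e})",
        ]
        for i, (p, v) in enumerate(mix.components, start=1):
            lines.append(f"component {i}:          weight {p:.3f}, variance {v:.4e}")
        lines += [
            f"susceptibility SNPs:  {est.n_susceptibility:.0f}"
            f" (SE {est.n_susceptibility_se:.0f})",
            f"h2 (log-OR scale):    {est.h2:.4f} (SE {est.h2_se:.4f})",
            f"  mixture part:       {est.h2_mixture:.4f}",
            f"  large-effect add-back: {est.add_back:.4f} ({est.n_large} SNPs)",
            f"upsilon:              {est.upsilon:.3f}" if mix.n_components == 3
            else "upsilon:              NA (two-component model)",
            "=" * 58,
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional interface


def fit_mixture(records, n_eff: float, n_components: int = 2,
                init_grid=None, seed: int = 0, M: int | None = None,
                ld_scores=None) -> MixtureResults:
    """Fit the effect-size mixture to cleaned summary statistics.

    Thin wrapper over :class:`EffectSizeMixture` for pipeline use; accepts a
    summary-statistic DataFrame (``Z`` column) or a bare z array.
    """
    model = EffectSizeMixture(records, n_eff=n_eff, M=M,
                              n_components=n_components, ld_scores=ld_scores)
    return model.fit(init_grid=init_grid, seed=seed)


def select_model(fit2: MixtureResults, fit3: MixtureResults,
                 rule: str = "bic") -> tuple[MixtureResults, str]:
    """Choose between the two- and three-component fits.

    The default rule is BIC with the SNP count as sample size; ties (and
    equal likelihoods) favour the two-component model by parsimony.
    """
    if fit2.model.nobs != fit3.model.nobs:
        raise ValueError("fits must be on the same records")
    if rule == "bic":
        three_wins = fit3.bic < fit2.bic
    elif rule == "aic":
        three_wins = fit3.aic < fit2.aic
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    if three_wins:
        return fit3, "three-component"
    return fit2, "two-component"


def total_heritability(model: MixtureModel,
                       large: LargeEffectSet | None = None,
                       results: MixtureResults | None = None) -> HeritabilityEstimate:
    """h2 = M pi_c E(beta^2) + sum_i (beta_i^2 - tau_i^2), with SEs.

    Negative per-SNP add-back terms (beta^2 < tau^2) are clamped at zero
    with a warning.  SEs come from the delta method when fit ``results``
    are supplied (the add-back is treated as a constant); otherwise NaN.
    """
    add_back = large.add_back if large is not None else 0.0
    n_large = len(large) if large is not None else 0
    h2_se = results.h2_se if results is not None else np.nan
    n_se = results.n_susceptibility_se if results is not None else np.nan
    return HeritabilityEstimate(
        h2=model.h2 + add_back,
        h2_se=h2_se,
        n_susceptibility=model.n_susceptibility + n_large,
        n_susceptibility_se=n_se,
        upsilon=model.upsilon,
        add_back=add_back,
        n_large=n_large,
        h2_mixture=model.h2,
    )
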