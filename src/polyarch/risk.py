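"""Risk stratification from PRS variance.

Converts the variance ``h2_prs`` of a polygenic risk score (on the
log-odds-ratio scale) into

* discrimination: ``AUC = Phi(sqrt(h2_prs / 2))`` under the model in which
  the PRS is normally distributed and shifts case and control distributions
  by ``h2_prs``;
* tail relative risk: ``RR(q) = exp(-h2_prs/2 + Phi^-1(q) * sqrt(h2_prs))``,
  the risk of an individual at the q-th PRS percentile relative to the
  population average under a multiplicative (log-linear) risk model;
* absolute residual lifetime risk up to age 80, combining age-specific
  incidence with the competing risk of all-cause mortality in a discrete
  one-year life-table computation, averaged over a baseline-age
  distribution.

The multiplicative model sets the individual hazard to
``lambda(t | r) = lambda_pop(t) * exp(r - h2_prs/2)`` with
``r = sqrt(h2_prs) * z`` for a standard-normal PRS quantile ``z``.  The
``exp(-h2_prs/2)`` factor calibrates the baseline so that the
population-average hazard multiplier is exactly 1
(``E[exp(r - h2/2)] = 1`` for ``r ~ N(0, h2)``), which preserves the
marginal incidence in the rare-disease limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LifeTables:
    """Age-specific incidence and mortality plus baseline-age weights.

    Parameters
    ----------
    ages : array of int
        Contiguous integer age grid in years, e.g. 30..80.  The hazard at
        ``ages[i]`` applies to the one-year interval ``[ages[i], ages[i]+1)``.
    incidence : array
        Cause-specific (disease) incidence hazard per year, one per age.
    mortality : array
        All-cause mortality hazard per year, one per age.
    weights : DataFrame
        Baseline-age weights with columns ``age_lo``, ``age_hi``, ``weight``
        over 5-year categories; weights sum to 1.
    """

    ages: np.ndarray
    incidence: np.ndarray
    mortality: np.ndarray
    weights: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.incidence = np.asarray(self.incidence, dtype=float)
        self.mortality = np.asarray(self.mortality, dtype=float)
        if self.ages.ndim != 1 or len(self.ages) == 0:
            raise ValueError("age grid must be a nonempty 1-D array")
        if np.any(np.diff(self.ages) != 1):
            raise ValueError("age grid must be contiguous integer years")
        if len(self.incidence) != len(self.ages) or len(self.mortality) != len(self.ages):
            raise ValueError("incidence/mortality must match the age grid")
        if np.any(self.incidence < 0) or np.any(self.mortality < 0):
            raise ValueError("hazards must be nonnegative")
        w = np.asarray(self.weights["weight"], dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("baseline-age weights must be nonnegative and sum to 1")

    def hazard_slice(self, age_start: int) -> tuple[np.ndarray, np.ndarray]:
        """Incidence and mortality hazards for ages ``[age_start, max_age)``."""
        i0 = int(age_start) - int(self.ages[0])
        if i0 < 0 or i0 >= len(self.ages):
            raise ValueError(f"age_start {age_start} outside the table's age grid")
        return self.incidence[i0:], self.mortality[i0:]


def auc_from_h2(h2_prs: float) -> float:
    """Best-achievable area under the ROC curve for a PRS of variance h2_prs.

    ``AUC = Phi(sqrt(h2_prs / 2))``: the probability that a random case
    scores above a random control when the PRS is normal and case/control
    means differ by ``h2_prs`` with common variance ``h2_prs``.
    """
    if h2_prs < 0:
        raise ValueError(f"h2_prs must be nonnegative, got {h2_prs}")
    return float(stats.norm.cdf(np.sqrt(h2_prs / 2.0)))


def rr_top_percentile(h2_prs: float, q: float = 0.99) -> float:
    """Relative risk at the q-th PRS percentile versus the population average.

    ``RR = exp(-h2_prs/2 + Phi^-1(q) * sqrt(h2_prs))`` under the log-linear
    risk model; equals 1 when the PRS carries no variance.
    """
    if h2_prs < 0:
        raise ValueError(f"h2_prs must be nonnegative, got {h2_prs}")
    if not 0.0 < q < 1.0:
        raise ValueError(f"percentile q must lie in (0, 1), got {q}")
    return float(np.exp(-h2_prs / 2.0 + stats.norm.ppf(q) * np.sqrt(h2_prs)))


def residual_lifetime_risk(
    prs_z: float,
    age_start: int,
    tables: LifeTables,
    h2_prs: float,
    max_age: int = 80,
) -> float:
    """Probability of disease onset between ``age_start`` and ``max_age``.

    Discrete one-year life-table recursion with competing mortality: within
    each year the disease strikes with probability ``lambda(t|r)`` and, if
    not, the individual survives to the next year with probability
    ``(1 - lambda(t|r)) * (1 - mu(t))``.  The individual hazard is
    ``lambda_pop(t) * exp(r - h2_prs/2)`` with ``r = sqrt(h2_prs) * prs_z``.
    """
    if h2_prs < 0:
        raise ValueError("h2_prs must be nonnegative")
    lam_pop, mu = tables.hazard_slice(age_start)
    n_years = min(len(lam_pop), max_age - int(age_start))
    if n_years <= 0:
        return 0.0
    multiplier = np.exp(np.sqrt(h2_prs) * prs_z - h2_prs / 2.0)
    lam = lam_pop[:n_years] * multiplier
    if np.any(lam > 1.0):
        warnings.warn(
            "per-interval disease probability exceeded 1; clamping", RuntimeWarning
        )
        lam = np.minimum(lam, 1.0)
    mu = np.minimum(mu[:n_years], 1.0)
    surv = np.empty(n_years)
    surv[0] = 1.0
    if n_years > 1:
        surv[1:] = np.cumprod((1.0 - lam) * (1.0 - mu))[:-1]
    return float(np.sum(lam * surv))


def _weighted_risk(prs_z: float, tables: LifeTables, h2_prs: float, max_age: int) -> float:
    # baseline age of each 5-year category is its lower bound
    total = 0.0
    for _, row in tables.weights.iterrows():
        total += row["weight"] * residual_lifetime_risk(
            prs_z, int(row["age_lo"]), tables, h2_prs, max_age=max_age
        )
    return total


def risk_distribution(
    h2_prs: float,
    tables: LifeTables,
    percentiles: np.ndarray | None = None,
    max_age: int = 80,
) -> pd.DataFrame:
    """Residual lifetime risk across PRS percentiles, averaged over baseline ages.

    Returns a DataFrame with columns ``percentile`` (1..99 by default) and
    ``lifetime_risk``.  Each percentile p is represented by the PRS quantile
    ``z = Phi^-1(p / 100)``; the risk at each percentile is the weighted
    average over the baseline-age categories of the life tables.
    """
    if percentiles is None:
        percentiles = np.arange(1, 100)
    percentiles = np.asarray(percentiles)
    zs = stats.norm.ppf(percentiles / 100.0)
    risks = [_weighted_risk(z, tables, h2_prs, max_age) for z in zs]
    return pd.DataFrame({"percentile": percentiles, "lifetime_risk": risks})
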