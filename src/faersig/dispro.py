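"""Disproportionality statistics for drug–event pairs.

Each drug–event pair is summarized by a 2×2 contingency table against the
reference background:

============  ==============  ==============
              target event    other events
============  ==============  ==============
target drug   a               b
other drugs   c               d
============  ==============  ==============

with N = a+b+c+d and expected count E = (a+b)(a+c)/N under independence.
Four estimators are provided:

* **ROR** — reporting odds ratio (a·d)/(b·c) with the Woolf log-normal 95%
  interval; a Haldane–Anscombe +0.5 correction is applied to all four cells
  when any cell is zero.
* **PRR** — proportional reporting ratio [a/(a+b)]/[c/(c+d)] with the
  Yates-corrected Pearson chi-square.
* **BCPNN IC** — information component log2((a+0.5)/(E+0.5)); its lower
  credibility bound IC025 uses either the Norén power-series approximation
  (default) or exact quantile inversion of the Gamma(a+0.5, E+0.5) posterior.
* **EBGM** — DuMouchel's multi-item gamma-Poisson shrinker: the observed
  counts are modelled as a ~ Poisson(λE) with λ drawn from a two-component
  gamma mixture whose five hyperparameters are estimated by maximizing the
  negative-binomial marginal likelihood over all pairs; EBGM is the posterior
  geometric mean of λ and EB05 its 5th posterior percentile.

Default positive-signal criteria: ROR/BCPNN joint signal when the ROR 95%
lower bound exceeds 1 AND IC025 exceeds 0; PRR signal when PRR ≥ 2, χ² ≥ 4
and a ≥ 3; EBGM signal when EB05 > 2.  All thresholds are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from faersig.cohort import case_mask

__all__ = [
    "ContingencyTable",
    "MGPSPrior",
    "SignalCriteria",
    "build_contingency",
    "ror_with_ci",
    "prr_with_chi2",
    "bcpnn_ic",
    "mgps_fit_prior",
    "ebgm_score",
    "evaluate_signals",
    "signal_screen",
]

#: two-sided 95% normal quantile, kept at full precision internally
Z_95 = 1.959964


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 report counts for one drug–event pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v}")
        if self.n == 0:
            raise ValueError("empty table (N=0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """E = (a+b)(a+c)/N, the count expected under independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    def corrected(self) -> tuple[float, float, float, float]:
        """Haldane–Anscombe cells: +0.5 everywhere iff any cell is zero."""
        if 0 in (self.a, self.b, self.c, self.d):
            return (self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)
        return (float(self.a), float(self.b), float(self.c), float(self.d))


def build_contingency(
    reference: pd.DataFrame, drug: str, target_pt: str
) -> ContingencyTable:
    """Count the 2×2 table for ``drug`` × ``target_pt`` in the reference.

    "Other drugs" is the report-level complement — reports not labeled with
    the target drug — so with multi-drug reports the four cells still sum to
    the reference report count.
    """
    exposed = reference["asms"].apply(lambda t, d=drug: d in t).to_numpy()
    if not exposed.any():
        raise ValueError(f"no exposed reports for drug {drug!r}")
    case = case_mask(reference, target_pt).to_numpy()
    a = int((exposed & case).sum())
    b = int((exposed & ~case).sum())
    c = int((~exposed & case).sum())
    d = int((~exposed & ~case).sum())
    return ContingencyTable(a, b, c, d)


def ror_with_ci(
    t: ContingencyTable, z: float = Z_95, correction: bool = True
) -> tuple[float, float, float]:
    """Reporting odds ratio with the Woolf 95% confidence interval.

    Returns ``(ror, lo, hi)`` where the interval is
    exp(ln ROR ± z·sqrt(1/a + 1/b + 1/c + 1/d)) on the (possibly
    Haldane-corrected) cells.
    """
    a, b, c, d = t.corrected() if correction else (t.a, t.b, t.c, t.d)
    if b * c == 0 or a * d == 0:
        raise ValueError("zero cell without continuity correction")
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(ror) - z * se)
    hi = math.exp(math.log(ror) + z * se)
    return ror, lo, hi


def prr_with_chi2(
    t: ContingencyTable, correction: bool = True, yates: bool = True
) -> tuple[float, float]:
    """Proportional reporting ratio and the (Yates-corrected) chi-square.

    PRR = [a/(a+b)] / [c/(c+d)]; χ² = N(|ad−bc|−N/2)²/[(a+b)(c+d)(a+c)(b+d)],
    floored at zero when |ad−bc| ≤ N/2.  When the event margin is empty
    (a+c = 0) the ratio is undefined and NaN is returned with χ² = 0.
    """
    if t.a + t.c == 0:
        return float("nan"), 0.0
    a, b, c, d = t.corrected() if correction else (t.a, t.b, t.c, t.d)
    if a + b == 0 or c + d == 0:
        raise ValueError("empty drug margin")
    prr = (a / (a + b)) / (c / (c + d))
    n = a + b + c + d
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2, 0.0)
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = n * diff * diff / denom if denom > 0 else 0.0
    return prr, chi2


def bcpnn_ic(
    t: ContingencyTable, mode: Literal["approx", "exact"] = "approx"
) -> tuple[float, float]:
    """BCPNN information component and its lower 95% credibility bound.

    IC = log2((a+0.5)/(E+0.5)) with E = (a+b)(a+c)/N.  In ``approx`` mode
    the lower bound follows the Norén power-series form
    IC025 ≈ IC − 3.3·(a+0.5)^(−1/2) − 2·(a+0.5)^(−3/2); in ``exact`` mode it
    is log2 of the 2.5th percentile of the Gamma(shape a+0.5, rate E+0.5)
    posterior for the observed/expected ratio λ.
    """
    e = t.expected
    ic = math.log2((t.a + 0.5) / (e + 0.5))
    if mode == "approx":
        s = t.a + 0.5
        ic025 = ic - 3.3 * s ** (-0.5) - 2.0 * s ** (-1.5)
    elif mode == "exact":
        lam025 = stats.gamma.ppf(0.025, t.a + 0.5, scale=1.0 / (e + 0.5))
        ic025 = math.log2(lam025)
    else:
        raise ValueError(f"unknown BCPNN mode {mode!r}")
    return ic, ic025


# --------------------------------------------------------------------------
# MGPS / EBGM layer
# --------------------------------------------------------------------------

#: documented deterministic starting point (alpha1, beta1, alpha2, beta2, w)
MGPS_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


@dataclass(frozen=True)
class MGPSPrior:
    """Two-component gamma mixture prior for the Poisson rate ratio λ.

    λ ~ w·Gamma(alpha1, rate beta1) + (1−w)·Gamma(alpha2, rate beta2).
    ``converged`` and ``loglik`` record the marginal-likelihood fit.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float
    converged: bool = True
    loglik: float = float("nan")
    n_pairs: int = 0

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        if not 0 < self.w < 1:
            raise ValueError("mixture weight must lie in (0,1)")

    @property
    def mean(self) -> float:
        """Prior mixture mean of λ."""
        return self.w * self.alpha1 / self.beta1 + (1 - self.w) * self.alpha2 / self.beta2


def _nb_loglik_components(a, e, alpha1, beta1, alpha2, beta2):
    """Per-pair log marginal likelihood of each mixture component.

    Marginalizing Poisson(λE) over λ ~ Gamma(alpha, beta) gives a negative
    binomial with size alpha and success probability beta/(beta+E).
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    l1 = stats.nbinom.logpmf(a, alpha1, beta1 / (beta1 + e))
    l2 = stats.nbinom.logpmf(a, alpha2, beta2 / (beta2 + e))
    return l1, l2


def _mixture_loglik(theta, a, e):
    la1, lb1, la2, lb2, logit_w = theta
    alpha1, beta1 = math.exp(la1), math.exp(lb1)
    alpha2, beta2 = math.exp(la2), math.exp(lb2)
    w = special.expit(logit_w)
    l1, l2 = _nb_loglik_components(a, e, alpha1, beta1, alpha2, beta2)
    both = np.stack([l1 + math.log(w), l2 + math.log1p(-w)])
    return float(special.logsumexp(both, axis=0).sum())


def mgps_fit_prior(
    a: Sequence[int],
    e: Sequence[float],
    start: tuple[float, float, float, float, float] = MGPS_START,
) -> MGPSPrior:
    """Fit the five MGPS hyperparameters by marginal maximum likelihood.

    Parameters are optimized on the log scale (logit scale for the weight)
    with L-BFGS-B from the fixed documented starting point, so the fit is
    deterministic.  Requires at least two pairs and strictly positive
    expected counts.
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    if a.shape != e.shape or a.ndim != 1:
        raise ValueError("a and e must be 1-D and the same length")
    if len(a) < 2:
        raise ValueError("MGPS fit needs at least 2 drug-event pairs")
    if np.any(e <= 0):
        raise ValueError("all expected counts must be > 0")

    a1, b1, a2, b2, w = start
    theta0 = np.array([math.log(a1), math.log(b1), math.log(a2), math.log(b2),
                       special.logit(w)])
    bounds = [(-12.0, 12.0)] * 4 + [(-12.0, 12.0)]

    res = optimize.minimize(
        lambda th: -_mixture_loglik(th, a, e),
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
    )
    la1, lb1, la2, lb2, lw = res.x
    return MGPSPrior(
        alpha1=math.exp(la1),
        beta1=math.exp(lb1),
        alpha2=math.exp(la2),
        beta2=math.exp(lb2),
        w=float(special.expit(lw)),
        converged=bool(res.success),
        loglik=float(-res.fun),
        n_pairs=int(len(a)),
    )


def _posterior_mixture(a: float, e: float, prior: MGPSPrior):
    """Posterior of λ given a: mixture of Gamma(alpha_j+a, beta_j+E)."""
    l1, l2 = _nb_loglik_components(
        a, e, prior.alpha1, prior.beta1, prior.alpha2, prior.beta2
    )
    logq = (math.log(prior.w) + float(l1)) - float(
        special.logsumexp([math.log(prior.w) + float(l1),
                           math.log1p(-prior.w) + float(l2)])
    )
    q = math.exp(logq)
    shapes = (prior.alpha1 + a, prior.alpha2 + a)
    rates = (prior.beta1 + e, prior.beta2 + e)
    return q, shapes, rates


def ebgm_score(
    a: int,
    e: float,
    prior: MGPSPrior,
    allow_nonconverged: bool = False,
) -> tuple[float, float]:
    """Empirical-Bayes geometric mean and 5th posterior percentile of λ.

    EBGM = 2^{E[log2 λ | a]}, computed through the digamma function
    (per component E[ln λ] = ψ(alpha_j + a) − ln(beta_j + E)); EB05 is found
    by root-finding on the posterior-mixture CDF.
    """
    if not prior.converged and not allow_nonconverged:
        raise ValueError(
            "MGPS prior did not converge; pass allow_nonconverged=True to override"
        )
    if e <= 0:
        raise ValueError("expected count must be > 0")
    q, (s1, s2), (r1, r2) = _posterior_mixture(a, e, prior)
    mean_ln = q * (special.digamma(s1) - math.log(r1)) + (1 - q) * (
        special.digamma(s2) - math.log(r2)
    )
    ebgm = math.exp(mean_ln)

    eb05 = _mixture_ppf(q, (s1, s2), (r1, r2), 0.05)
    return ebgm, eb05


def _mixture_ppf(q: float, shapes, rates, p: float) -> float:
    """Quantile of q·Gamma(s1,r1) + (1−q)·Gamma(s2,r2) by root-finding.

    The mixture quantile always lies between the two component quantiles,
    which gives a bracket that stays valid even for degenerate fitted priors
    (component quantiles can underflow to 0; the CDF is still monotone).
    """
    (s1, s2), (r1, r2) = shapes, rates

    def cdf(x: float) -> float:
        return q * stats.gamma.cdf(x, s1, scale=1 / r1) + (1 - q) * stats.gamma.cdf(
            x, s2, scale=1 / r2
        )

    q1 = float(stats.gamma.ppf(p, s1, scale=1 / r1))
    q2 = float(stats.gamma.ppf(p, s2, scale=1 / r2))
    lo, hi = min(q1, q2), max(q1, q2)
    if hi <= lo:
        return lo
    # brentq needs a strict sign change; endpoints may sit exactly on the root
    flo, fhi = cdf(lo) - p, cdf(hi) - p
    if flo >= 0:
        return lo
    if fhi <= 0:
        return hi
    return optimize.brentq(lambda x: cdf(x) - p, lo, hi, xtol=1e-12, rtol=1e-12)


def ebgm_quantile(
    a: int, e: float, prior: MGPSPrior, p: float, allow_nonconverged: bool = False
) -> float:
    """Arbitrary posterior quantile of λ (used for EB95-style bounds)."""
    if not prior.converged and not allow_nonconverged:
        raise ValueError("MGPS prior did not converge")
    q, shapes, rates = _posterior_mixture(a, e, prior)
    return _mixture_ppf(q, shapes, rates, p)


# --------------------------------------------------------------------------
# Signal criteria
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SignalCriteria:
    """Thresholds defining a positive signal for each algorithm."""

    ror_lo_gt: float = 1.0
    ic025_gt: float = 0.0
    prr_ge: float = 2.0
    chi2_ge: float = 4.0
    min_cases: int = 3
    eb05_gt: float = 2.0


def evaluate_signals(
    a: int,
    ror_lo95: float,
    ic025: float,
    prr: float,
    chi2: float,
    eb05: float | None,
    criteria: SignalCriteria = SignalCriteria(),
) -> dict[str, bool]:
    """Apply the positive-signal criteria to one pair's statistics.

    * ``ror_bcpnn_positive`` — ROR 95% lower bound > 1 AND IC025 > 0 (the
      joint frequentist/Bayesian primary criterion);
    * ``prr_positive`` — PRR ≥ 2 AND χ² ≥ 4 AND at least 3 cases;
    * ``ebgm_positive`` — EB05 > 2 (False when EB05 is unavailable).

    NaN statistics never satisfy a criterion.
    """
    ror_bcpnn = bool(
        ror_lo95 > criteria.ror_lo_gt and ic025 > criteria.ic025_gt
    )
    prr_pos = bool(
        not math.isnan(prr)
        and prr >= criteria.prr_ge
        and chi2 >= criteria.chi2_ge
        and a >= criteria.min_cases
    )
    ebgm_pos = bool(eb05 is not None and not math.isnan(eb05) and eb05 > criteria.eb05_gt)
    return {
        "ror_bcpnn_positive": ror_bcpnn,
        "prr_positive": prr_pos,
        "ebgm_positive": ebgm_pos,
    }


def signal_screen(
    reference: pd.DataFrame,
    target_pt: str,
    drugs: Sequence[str] | None = None,
    bcpnn_mode: Literal["approx", "exact"] = "approx",
    criteria: SignalCriteria = SignalCriteria(),
    fit_mgps: bool = True,
    correction: bool = True,
) -> pd.DataFrame:
    """Compute all four statistics and criterion flags for every drug.

    Returns one row per drug with the 2×2 cells, E, ROR (with CI), PRR/χ²,
    IC/IC025, EBGM/EB05 (when ``fit_mgps``) and the three boolean flags.
    The MGPS prior is fitted on the (a, E) pairs of this screen.
    """
    if drugs is None:
        drugs = sorted({d for t in reference["asms"] for d in t})
    tables = {d: build_contingency(reference, d, target_pt) for d in drugs}

    # MGPS needs strictly positive expected counts; pairs with an empty
    # event margin (E = 0) are excluded from the fit and get NaN scores
    prior = None
    fit_pairs = [t for t in tables.values() if t.expected > 0]
    if fit_mgps and len(fit_pairs) >= 2:
        prior = mgps_fit_prior(
            [t.a for t in fit_pairs],
            [t.expected for t in fit_pairs],
        )

    rows = []
    for d in drugs:
        t = tables[d]
        ror, lo, hi = ror_with_ci(t, correction=correction)
        prr, chi2 = prr_with_chi2(t, correction=correction)
        ic, ic025 = bcpnn_ic(t, mode=bcpnn_mode)
        if prior is not None and t.expected > 0:
            ebgm, eb05 = ebgm_score(t.a, t.expected, prior,
                                    allow_nonconverged=not prior.converged)
        else:
            ebgm = eb05 = float("nan")
        flags = evaluate_signals(t.a, lo, ic025, prr, chi2, eb05, criteria)
        rows.append({
            "drug": d, "pt": target_pt,
            "a": t.a, "b": t.b, "c": t.c, "d": t.d, "expected": t.expected,
            "ror": ror, "ror_lo95": lo, "ror_hi95": hi,
            "prr": prr, "chi2": chi2,
            "ic": ic, "ic025": ic025,
            "ebgm": ebgm, "eb05": eb05,
            **flags,
        })
    return pd.DataFrame(rows)
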