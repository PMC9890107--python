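"""Frequentist tests of the design: random-intercept logistic regression
with a Wald CI on the probability scale, the Bonferroni look schedule, and
the one-sided exact proportion tests used as robustness checks.

The mixed model is the intercept-only binomial GLMM

    success_ij ~ Bernoulli(logit^{-1}(beta0 + u_i)),   u_i ~ N(0, tau^2),

whose marginal likelihood factorizes over participants and depends on each
participant only through the sufficient pattern (successes_i, trials_i).
Collapsing identical patterns makes the likelihood a weighted sum over at
most a handful of distinct patterns (19 when everyone completes 18 trials),
which is what makes large-scale design simulation tractable.

Each pattern's one-dimensional integral over the random intercept is
evaluated by adaptive Gauss–Hermite quadrature: the integrand is centred
at its mode and scaled by its curvature before applying the quadrature
rule, so a modest number of nodes (21) is accurate across the whole
(beta0, tau) plane, including near the tau -> 0 boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import optimize, special, stats

from .verdicts import Verdict

__all__ = [
    "MixedModelFit",
    "ProbabilityCI",
    "collapse_patterns",
    "marginal_loglik",
    "fit_random_intercept_logistic",
    "fit_patterns",
    "probability_ci",
    "ci_verdict",
    "ci_level_for_look",
    "one_sided_proportion_tests",
    "ProportionTestResult",
]

_GH_NODES = 21
_gh_x, _gh_w = np.polynomial.hermite.hermgauss(_GH_NODES)
_gh_logw = np.log(_gh_w) + _gh_x**2  # fold e^{x^2} into log weights

_TAU_FLOOR = 1e-6  # below this the model is treated as fixed-effects


@dataclass(frozen=True)
class MixedModelFit:
    """Maximum-likelihood fit of the intercept-only binomial GLMM."""

    beta0: float
    tau: float
    se_beta0: float
    loglik: float
    n_participants: int
    n_trials: int
    converged: bool


@dataclass(frozen=True)
class ProbabilityCI:
    """Wald confidence interval mapped to the probability scale."""

    level: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lo <= self.hi <= 1.0:
            raise ValueError("CI bounds must satisfy 0 <= lo <= hi <= 1")


def collapse_patterns(table) -> dict[tuple[int, int], int]:
    """Sufficient statistics: map (successes_i, trials_i) -> participant count."""
    if len(table.df) == 0:
        return {}
    g = table.df.groupby("participant_id", sort=False)["success"].agg(["sum", "count"])
    out: dict[tuple[int, int], int] = {}
    for s, c in zip(g["sum"].astype(int), g["count"].astype(int)):
        out[(s, c)] = out.get((s, c), 0) + 1
    return out


def _pattern_arrays(
    patterns: Mapping[tuple[int, int], int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ks = np.array([k for k, _ in patterns], dtype=float)
    ns = np.array([n for _, n in patterns], dtype=float)
    cs = np.array(list(patterns.values()), dtype=float)
    return ks, ns, cs


def _log_binom(ks: np.ndarray, ns: np.ndarray) -> np.ndarray:
    return (
        special.gammaln(ns + 1.0)
        - special.gammaln(ks + 1.0)
        - special.gammaln(ns - ks + 1.0)
    )


def _fixed_loglik(ks, ns, cs, beta0):
    eta = beta0
    return float(
        np.sum(cs * (ks * eta - ns * np.logaddexp(0.0, eta) + _log_binom(ks, ns)))
    )


def marginal_loglik(
    patterns: Mapping[tuple[int, int], int], beta0: float, tau: float
) -> float:
    """Marginal log-likelihood of the GLMM at (beta0, tau) on collapsed patterns.

    Includes the binomial coefficients, so values are comparable with
    trial-level (and external) computations.  tau below the numerical floor
    is evaluated as the fixed-effects binomial likelihood (exact limit).
    """
    if not patterns:
        return 0.0
    ks, ns, cs = _pattern_arrays(patterns)
    return _marginal_loglik_arrays(ks, ns, cs, beta0, tau)


def _marginal_loglik_arrays(ks, ns, cs, beta0: float, tau: float) -> float:
    if tau < _TAU_FLOOR:
        return _fixed_loglik(ks, ns, cs, beta0)
    inv_t2 = 1.0 / (tau * tau)

    # Per-pattern Laplace centring: Newton on the log-integrand's mode.
    u = np.zeros_like(ks)
    for _ in range(30):
        p = special.expit(beta0 + u)
        grad = ks - ns * p - u * inv_t2
        hess = -ns * p * (1.0 - p) - inv_t2
        step = grad / hess
        u -= step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = special.expit(beta0 + u)
    sigma = 1.0 / np.sqrt(ns * p * (1.0 - p) + inv_t2)

    # Adaptive GH: u_ij = u_i + sqrt(2) sigma_i x_j
    uj = u[:, None] + math.sqrt(2.0) * sigma[:, None] * _gh_x[None, :]
    eta = beta0 + uj
    logf = (
        ks[:, None] * eta
        - ns[:, None] * np.logaddexp(0.0, eta)
        - 0.5 * uj * uj * inv_t2
    )
    log_int = special.logsumexp(logf + _gh_logw[None, :], axis=1)
    log_int += 0.5 * math.log(2.0) + np.log(sigma) - 0.5 * math.log(2.0 * math.pi) - math.log(tau)
    return float(np.sum(cs * (log_int + _log_binom(ks, ns))))


def fit_patterns(patterns: Mapping[tuple[int, int], int]) -> MixedModelFit:
    """Fit the GLMM by maximizing the marginal likelihood over (beta0, tau).

    The tau = 0 boundary is handled by profile comparison: the fixed-effects
    solution is computed in closed form and kept whenever the interior
    optimizer cannot beat it.  The standard error of beta0 comes from the
    observed information (numerical Hessian) of the marginal likelihood at
    the optimum; at the boundary this reduces to the binomial information.
    """
    if not patterns:
        raise ValueError("cannot fit a model to an empty table")
    ks, ns, cs = _pattern_arrays(patterns)
    n_participants = int(cs.sum())
    n_trials = int((ns * cs).sum())
    k_total = float((ks * cs).sum())
    if k_total == 0 or k_total == n_trials:
        # Separation: beta0 diverges; flag rather than report a silent estimate.
        return MixedModelFit(
            beta0=math.copysign(math.inf, k_total - n_trials / 2.0),
            tau=0.0,
            se_beta0=math.nan,
            loglik=0.0,
            n_participants=n_participants,
            n_trials=n_trials,
            converged=False,
        )

    phat = k_total / n_trials
    beta0_fixed = special.logit(phat)
    ll_fixed = _fixed_loglik(ks, ns, cs, beta0_fixed)

    def negll(theta):
        return -_marginal_loglik_arrays(ks, ns, cs, theta[0], theta[1])

    best = None
    for tau0 in (0.1, 0.6):
        res = optimize.minimize(
            negll,
            x0=np.array([beta0_fixed, tau0]),
            method="L-BFGS-B",
            bounds=[(None, None), (0.0, 15.0)],
            options={"ftol": 1e-11, "gtol": 1e-8, "maxiter": 200},
        )
        if best is None or res.fun < best.fun:
            best = res
        if best.fun < -ll_fixed - 1e-9:
            break  # interior optimum already beats the boundary
    converged = bool(best.success)
    if not converged:
        # Gradient-free polish: the surface is almost flat in tau near the
        # boundary and finite-difference line searches can stall there.
        res = optimize.minimize(
            negll,
            x0=best.x,
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 400},
        )
        if res.fun <= best.fun:
            best = res
        converged = bool(res.success)

    beta0_hat, tau_hat = float(best.x[0]), float(max(best.x[1], 0.0))
    ll_hat = -float(best.fun)

    if ll_fixed >= ll_hat - 1e-9 or tau_hat < _TAU_FLOOR:
        # Boundary solution: fixed-effects binomial fit.
        se = 1.0 / math.sqrt(n_trials * phat * (1.0 - phat))
        return MixedModelFit(
            beta0=float(beta0_fixed),
            tau=0.0,
            se_beta0=se,
            loglik=ll_fixed,
            n_participants=n_participants,
            n_trials=n_trials,
            converged=True,
        )

    se = _wald_se(ks, ns, cs, beta0_hat, tau_hat)
    if not math.isfinite(se) or se <= 0:
        converged = False
        se = math.nan
    return MixedModelFit(
        beta0=beta0_hat,
        tau=tau_hat,
        se_beta0=se,
        loglik=ll_hat,
        n_participants=n_participants,
        n_trials=n_trials,
        converged=converged,
    )


def _wald_se(ks, ns, cs, beta0: float, tau: float) -> float:
    """SE of beta0 from the 2x2 observed information of the marginal loglik."""
    h_b = 1e-5 * max(1.0, abs(beta0))
    h_t = 1e-5 * max(0.05, tau)

    def ll(b, t):
        return _marginal_loglik_arrays(ks, ns, cs, b, max(t, _TAU_FLOOR))

    f0 = ll(beta0, tau)
    d_bb = (ll(beta0 + h_b, tau) - 2.0 * f0 + ll(beta0 - h_b, tau)) / h_b**2
    d_tt = (ll(beta0, tau + h_t) - 2.0 * f0 + ll(beta0, tau - h_t)) / h_t**2
    d_bt = (
        ll(beta0 + h_b, tau + h_t)
        - ll(beta0 + h_b, tau - h_t)
        - ll(beta0 - h_b, tau + h_t)
        + ll(beta0 - h_b, tau - h_t)
    ) / (4.0 * h_b * h_t)
    info = -np.array([[d_bb, d_bt], [d_bt, d_tt]])
    try:
        cov = np.linalg.inv(info)
        var = cov[0, 0]
    except np.linalg.LinAlgError:
        var = math.nan
    if not (math.isfinite(var) and var > 0):
        # tau direction flat (optimum hugging the boundary): profile out tau
        # and use the beta0-only observed information
        var = -1.0 / d_bb if d_bb < 0 else math.nan
    return math.sqrt(var) if var > 0 else math.nan


def fit_random_intercept_logistic(table) -> MixedModelFit:
    """Fit the GLMM to a confirmatory-filtered :class:`~psiseq.trial_data.TrialTable`."""
    return fit_patterns(collapse_patterns(table))


def probability_ci(fit: MixedModelFit, level: float) -> ProbabilityCI:
    """Wald CI for beta0 mapped through the inverse logit."""
    if not fit.converged:
        raise ValueError("cannot form a Wald CI from an unconverged fit")
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie strictly in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo = float(special.expit(fit.beta0 - z * fit.se_beta0))
    hi = float(special.expit(fit.beta0 + z * fit.se_beta0))
    return ProbabilityCI(level=level, lo=lo, hi=hi)


def ci_verdict(ci: ProbabilityCI, sesoi: float = 0.51, null: float = 0.50) -> Verdict:
    """Equivalence-style decision: M0 if the CI excludes the SESOI from above,
    otherwise M1 if it excludes the null from below, otherwise inconclusive."""
    if ci.hi < sesoi:
        return Verdict.SUPPORT_M0
    if ci.lo > null:
        return Verdict.SUPPORT_M1
    return Verdict.INCONCLUSIVE


def ci_level_for_look(look: int, base_alpha: float = 0.005) -> float:
    """Bonferroni-widened confidence level for the given 1-based look.

    Two CI-based decisions are made per look, so the per-look level is
    1 - base_alpha / (2 * look): 99.75%, 99.875%, 99.91667%, 99.9375%, ...
    """
    if look < 1:
        raise ValueError("look index is 1-based")
    return 1.0 - base_alpha / (2.0 * look)


@dataclass(frozen=True)
class ProportionTestResult:
    """One-sided proportion tests against the SESOI and the null bound."""

    verdict: Verdict
    p_le_sesoi: float  # P(X <= k | p = sesoi): rejects "p >= sesoi" when small
    p_gt_null: float  # P(X >= k | p = null): rejects "p <= null" when small


def one_sided_proportion_tests(
    k: int,
    n: int,
    sesoi: float = 0.51,
    null: float = 0.50,
    alpha: float = 0.005,
    exact: bool = True,
) -> ProportionTestResult:
    """Sequential pair of one-sided proportion tests (robustness check).

    First tests H0: p >= sesoi against p < sesoi (rejection supports M0);
    only if that fails, tests H0: p <= null against p > null (rejection
    supports M1).  Exact binomial tails by default; ``exact=False`` uses
    the normal approximation without continuity correction.
    """
    if n < 1:
        raise ValueError("need at least one trial")
    if exact:
        p_lo = float(stats.binom.cdf(k, n, sesoi))
        p_hi = float(stats.binom.sf(k - 1, n, null))
    else:
        p_lo = float(stats.norm.cdf((k / n - sesoi) / math.sqrt(sesoi * (1 - sesoi) / n)))
        p_hi = float(stats.norm.sf((k / n - null) / math.sqrt(null * (1 - null) / n)))
    if p_lo < alpha:
        verdict = Verdict.SUPPORT_M0
    elif p_hi < alpha:
        verdict = Verdict.SUPPORT_M1
    else:
        verdict = Verdict.INCONCLUSIVE
    return ProportionTestResult(verdict=verdict, p_le_sesoi=p_lo, p_gt_null=p_hi)
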