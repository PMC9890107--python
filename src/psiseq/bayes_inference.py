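"""Bayesian proportion tests for pooled binomial guess counts.

Two families live here:

* the Bayes factor BF01 contrasting the point null M0 (p = 0.5 on every
  erotic trial) with M1, whose prior on p is a beta density truncated to
  (0.5, 1) — see :mod:`psiseq.priors`.  With a truncated Beta(a, b) prior
  the marginal likelihood of k successes in n trials is available in
  closed form through regularized incomplete beta functions, so

      BF01 = 0.5^n * B(a, b) * (1 - I_0.5(a, b))
             / [ B(k + a, n - k + b) * (1 - I_0.5(k + a, n - k + b)) ]

  evaluated entirely in log space;

* the conjugate parameter-estimation robustness test: an *untruncated*
  Beta(829, 733) prior updated to Beta(829 + k, 733 + (n - k)), summarized
  by its mode, shortest 90% highest-density interval, and the posterior
  mass inside the region of practical equivalence [0, 0.506].

The BF priors are truncated but the robustness-test prior is deliberately
not: the registered update rule adds counts to the plain beta shapes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .priors import TruncatedBetaPrior
from .verdicts import Verdict

__all__ = [
    "bf01",
    "log_bf01",
    "bf_verdict",
    "posterior_update",
    "hdi",
    "rope_decision",
    "summarize_posterior",
    "BayesTestResult",
    "PosteriorSummary",
]

BF_UPPER_DEFAULT = 25.0
BF_LOWER_DEFAULT = 1.0 / 25.0


def log_bf01(k: int, n: int, prior: TruncatedBetaPrior) -> float:
    """log BF01 for k successes in n pooled trials against the point null.

    Defined as 0 (BF = 1) for the empty data set.  Returns ``+inf`` when the
    marginal likelihood under M1 underflows (evidence for M0 beyond double
    precision), which can only happen for success rates far below chance.
    """
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if n == 0:
        return 0.0
    a, b = prior.a, prior.b
    log_m0 = n * math.log(0.5)
    post_tail = special.betaincc(k + a, n - k + b, prior.lower)
    if post_tail <= 0.0:
        return math.inf
    log_m1 = (
        special.betaln(k + a, n - k + b)
        - special.betaln(a, b)
        + math.log(post_tail)
        - prior.log_tail_mass
    )
    return log_m0 - log_m1


def bf01(k: int, n: int, prior: TruncatedBetaPrior) -> float:
    """BF01 (evidence odds for M0 over M1); > 1 favours the null."""
    return float(np.exp(log_bf01(k, n, prior)))


def bf_verdict(
    bf: float,
    upper: float = BF_UPPER_DEFAULT,
    lower: float = BF_LOWER_DEFAULT,
) -> Verdict:
    """Map a BF01 value onto the registered three-way decision."""
    if not lower < 1.0 < upper:
        raise ValueError("thresholds must satisfy lower < 1 < upper")
    if bf > upper:
        return Verdict.SUPPORT_M0
    if bf < lower:
        return Verdict.SUPPORT_M1
    return Verdict.INCONCLUSIVE


@dataclass(frozen=True)
class BayesTestResult:
    """Per-prior BF01 values and verdicts for one pooled (k, n) count."""

    k: int
    n: int
    bf01_by_prior: dict[str, float]
    verdicts: dict[str, Verdict]


def bayes_proportion_tests(
    k: int,
    n: int,
    priors: tuple[TruncatedBetaPrior, ...],
    upper: float = BF_UPPER_DEFAULT,
    lower: float = BF_LOWER_DEFAULT,
) -> BayesTestResult:
    """Run the BF01 test under each prior and collect the verdicts."""
    bfs = {p.label: bf01(k, n, p) for p in priors}
    verdicts = {lab: bf_verdict(v, upper, lower) for lab, v in bfs.items()}
    return BayesTestResult(k=k, n=n, bf01_by_prior=bfs, verdicts=verdicts)


# ---------------------------------------------------------------------------
# Conjugate parameter-estimation robustness test


def posterior_update(
    k: int, n: int, prior_a: float = 829.0, prior_b: float = 733.0
) -> tuple[float, float]:
    """Conjugate beta update on the untruncated prior: shapes only."""
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    return (prior_a + k, prior_b + (n - k))


def hdi(post_a: float, post_b: float, level: float = 0.90) -> tuple[float, float]:
    """Shortest interval holding ``level`` posterior mass of Beta(a, b).

    Found by minimizing the interval width over the lower-tail mass of the
    left endpoint; requires a unimodal interior mode (both shapes > 1).
    """
    if post_a <= 1.0 or post_b <= 1.0:
        raise ValueError("HDI requires an interior mode (both shapes > 1)")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly in (0, 1)")
    dist = stats.beta(post_a, post_b)

    def width(t: float) -> float:
        return dist.ppf(t + level) - dist.ppf(t)

    res = optimize.minimize_scalar(
        width, bounds=(0.0, 1.0 - level), method="bounded",
        options={"xatol": 1e-12},
    )
    lo = float(dist.ppf(res.x))
    hi = float(dist.ppf(res.x + level))
    return lo, hi


@dataclass(frozen=True)
class PosteriorSummary:
    """Summary of the conjugate beta posterior and its ROPE decision."""

    post_a: float
    post_b: float
    mode: float
    hdi_level: float
    hdi_lo: float
    hdi_hi: float
    rope_hi: float
    mass_in_rope: float
    tail_above_rope: float
    verdict: Verdict


def rope_decision(
    post_a: float,
    post_b: float,
    rope_hi: float = 0.506,
    mass_threshold: float = 0.95,
) -> tuple[Verdict, float]:
    """ROPE rule on the posterior: returns (verdict, mass inside [0, rope_hi])."""
    inside = float(special.betainc(post_a, post_b, rope_hi))
    if inside > mass_threshold:
        return Verdict.SUPPORT_M0, inside
    if 1.0 - inside > mass_threshold:
        return Verdict.SUPPORT_M1, inside
    return Verdict.INCONCLUSIVE, inside


def summarize_posterior(
    k: int,
    n: int,
    prior_a: float = 829.0,
    prior_b: float = 733.0,
    hdi_level: float = 0.90,
    rope_hi: float = 0.506,
    mass_threshold: float = 0.95,
) -> PosteriorSummary:
    """Full robustness-test summary for pooled counts (k, n)."""
    post_a, post_b = posterior_update(k, n, prior_a, prior_b)
    mode = (post_a - 1.0) / (post_a + post_b - 2.0)
    lo, hi = hdi(post_a, post_b, hdi_level)
    verdict, inside = rope_decision(post_a, post_b, rope_hi, mass_threshold)
    return PosteriorSummary(
        post_a=post_a,
        post_b=post_b,
        mode=mode,
        hdi_level=hdi_level,
        hdi_lo=lo,
        hdi_hi=hi,
        rope_hi=rope_hi,
        mass_in_rope=inside,
        tail_above_rope=1.0 - inside,
        verdict=verdict,
    )
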