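"""One-sided beta priors for the success chance of a forced-choice guess.

The alternative model M1 states that the probability of a correct guess on
an erotic trial exceeds chance, so every prior lives on the open interval
(0.5, 1): an ordinary Beta(a, b) density truncated at 0.5 and renormalized.
Three named priors are in registered use:

* ``uniform`` — Beta(1, 1), i.e. flat on (0.5, 1);
* ``buj`` — the Bem–Utts–Johnson knowledge-based prior, Beta(7, 7), which
  places 90% of its truncated mass below p = 0.712 (the probability
  equivalent of a Cohen's d of 0.5);
* ``replication`` — Beta(829, 733), the posterior implied by the original
  experiment's 828 successes in 1560 trials under a flat prior.

All tail masses are computed through the regularized incomplete beta
function in log space so that shapes in the hundreds remain stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

__all__ = [
    "TruncatedBetaPrior",
    "d_to_probability",
    "probability_to_d",
    "make_prior",
    "truncated_quantile",
    "truncated_mass",
]

#: Cohen's d -> log-odds scaling constant (logistic/normal variance matching).
_D_TO_LOGODDS = math.pi / math.sqrt(3.0)

PRIOR_SHAPES = {
    "uniform": (1.0, 1.0),
    "buj": (7.0, 7.0),
    "replication": (829.0, 733.0),
}


def d_to_probability(d: float) -> float:
    """Convert a Cohen's d effect size to a success probability.

    Uses log-odds = d * pi / sqrt(3), then the inverse-logit. d = 0 maps to
    0.5 and the map is strictly increasing.
    """
    if not math.isfinite(d):
        raise ValueError("effect size must be finite")
    return float(special.expit(d * _D_TO_LOGODDS))


def probability_to_d(p: float) -> float:
    """Inverse of :func:`d_to_probability`; requires 0 < p < 1."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"probability must lie strictly in (0, 1), got {p}")
    return float(special.logit(p) / _D_TO_LOGODDS)


@dataclass(frozen=True)
class TruncatedBetaPrior:
    """Beta(a, b) density restricted and renormalized to (lower, 1)."""

    a: float
    b: float
    lower: float = 0.5
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("beta shapes must be positive")
        if not 0.0 <= self.lower < 1.0:
            raise ValueError("truncation bound must lie in [0, 1)")

    @property
    def log_tail_mass(self) -> float:
        """log P(X > lower) under the untruncated Beta(a, b)."""
        tail = special.betaincc(self.a, self.b, self.lower)
        if tail <= 0.0:
            raise ValueError("truncated prior has no mass above the bound")
        return float(np.log(tail))

    def pdf(self, p):
        p = np.asarray(p, dtype=float)
        out = np.where(
            (p > self.lower) & (p < 1.0),
            np.exp(stats.beta.logpdf(p, self.a, self.b) - self.log_tail_mass),
            0.0,
        )
        return out if out.ndim else float(out)

    def logpdf(self, p: float) -> float:
        if not self.lower < p < 1.0:
            return -math.inf
        return float(stats.beta.logpdf(p, self.a, self.b) - self.log_tail_mass)

    def cdf(self, p: float) -> float:
        """Truncated CDF: mass of (lower, p]."""
        return truncated_mass(self, self.lower, min(max(p, self.lower), 1.0))

    def ppf(self, q: float) -> float:
        return truncated_quantile(self, q)

    def mean(self) -> float:
        """Mean of the truncated distribution, by the tail-mass identity."""
        # E[p | p > c] = E[p] * P(X' > c) / P(X > c) with X' ~ Beta(a+1, b).
        log_num = (
            np.log(self.a / (self.a + self.b))
            + np.log(special.betaincc(self.a + 1.0, self.b, self.lower))
        )
        return float(np.exp(log_num - self.log_tail_mass))


def make_prior(
    label: str,
    successes: int | None = None,
    failures: int | None = None,
    a: float | None = None,
    b: float | None = None,
) -> TruncatedBetaPrior:
    """Construct one of the named priors (or a custom one) truncated at 0.5.

    The replication prior is built from observed counts of the seeding
    study — shapes (successes + 1, failures + 1) — defaulting to the
    828/732 split of the original experiment.
    """
    if label == "replication":
        successes = 828 if successes is None else successes
        failures = 732 if failures is None else failures
        return TruncatedBetaPrior(successes + 1.0, failures + 1.0, label=label)
    if label in ("uniform", "buj"):
        sa, sb = PRIOR_SHAPES[label]
        return TruncatedBetaPrior(sa, sb, label=label)
    if label == "custom":
        if a is None or b is None:
            raise ValueError("custom prior requires explicit shapes a, b")
        return TruncatedBetaPrior(float(a), float(b), label=label)
    raise ValueError(f"unknown prior label: {label!r}")


def default_priors() -> tuple[TruncatedBetaPrior, TruncatedBetaPrior, TruncatedBetaPrior]:
    """The three registered M1 priors, in (uniform, buj, replication) order."""
    return (make_prior("uniform"), make_prior("buj"), make_prior("replication"))


def truncated_mass(prior: TruncatedBetaPrior, lo: float, hi: float) -> float:
    """Probability mass the truncated prior assigns to [lo, hi]."""
    if not (prior.lower <= lo <= hi <= 1.0):
        raise ValueError(
            f"bounds must satisfy {prior.lower} <= lo <= hi <= 1, got ({lo}, {hi})"
        )
    num = special.betainc(prior.a, prior.b, hi) - special.betainc(prior.a, prior.b, lo)
    return float(np.clip(num * np.exp(-prior.log_tail_mass), 0.0, 1.0))


def truncated_quantile(prior: TruncatedBetaPrior, q: float) -> float:
    """Quantile of the truncated prior: truncated_mass(lower, result) == q."""
    if not 0.0 < q < 1.0:
        raise ValueError("quantile level must lie strictly in (0, 1)")
    mass_below = special.betainc(prior.a, prior.b, prior.lower)
    return float(stats.beta.ppf(mass_below + q * (1.0 - mass_below), prior.a, prior.b))
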