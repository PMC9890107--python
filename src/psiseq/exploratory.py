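"""Exploratory analyses: rate-distribution comparison and split-half correlation.

If guessing ability varied across people (the "sheep-goat" conjecture of
distinct above- and below-chance performers), the distribution of
per-participant success rates would be overdispersed relative to the
Binomial(18, 0.5)/18 reference, and performance on odd- and even-numbered
trials would correlate within participants.  Both diagnostics are
implemented here: the earth mover's (Wasserstein-1) distance between the
observed and simulated-null rate distributions, and the Pearson odd/even
split-half correlation with a Fisher-z interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import trial_data as td

__all__ = [
    "RateSample",
    "null_rate_reference",
    "observed_rate_sample",
    "earth_movers_distance",
    "odd_even_split_correlation",
]


@dataclass(frozen=True)
class RateSample:
    """Multiset of per-participant success rates on the k/trials grid."""

    values: np.ndarray
    source: str  # observed | simulated_null

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size and (v.min() < 0.0 or v.max() > 1.0):
            raise ValueError("success rates must lie in [0, 1]")
        object.__setattr__(self, "values", v)


def null_rate_reference(
    n_participants: int = 1_000_000,
    trials: int = 18,
    p: float = 0.5,
    rng: np.random.Generator | None = None,
) -> RateSample:
    """Simulated chance-only reference distribution of success rates.

    Draws ``n_participants`` values of Binomial(trials, p)/trials — the
    expected rate distribution under a homogeneous population guessing at
    probability ``p``.
    """
    if n_participants < 1:
        raise ValueError("need at least one simulated participant")
    rng = rng if rng is not None else np.random.default_rng()
    return RateSample(
        values=rng.binomial(trials, p, size=n_participants) / trials,
        source="simulated_null",
    )


def observed_rate_sample(table: td.TrialTable, required_trials: int = 18) -> RateSample:
    """Observed per-participant rates, complete participants only."""
    rates = td.participant_success_rates(table, required_trials)
    return RateSample(values=np.array(list(rates.values())), source="observed")


def earth_movers_distance(x: RateSample, y: RateSample) -> float:
    """Wasserstein-1 distance between two empirical rate distributions.

    Computed as the integral of |F_x - F_y| over [0, 1] (handles unequal
    sample sizes); symmetric, and zero iff the empirical distributions
    coincide.
    """
    if x.values.size == 0 or y.values.size == 0:
        raise ValueError("both rate samples must be nonempty")
    return float(stats.wasserstein_distance(x.values, y.values))


def odd_even_split_correlation(
    table: td.TrialTable, required_trials: int = 18
) -> tuple[float, float, float]:
    """Pearson correlation of odd- vs even-trial success rates per participant.

    "Odd" and "even" index the within-participant order of a participant's
    erotic trials (1-based).  Returns (r, ci_lo, ci_hi) with a 95% Fisher-z
    interval.  Requires at least 3 participants with the full trial count.
    """
    df = table.df
    odd_rates = []
    even_rates = []
    for _, g in df.groupby("participant_id", sort=True):
        succ = g.sort_values(["deposit_order", "trial_index"])["success"].to_numpy()
        if len(succ) != required_trials:
            continue
        odd_rates.append(succ[0::2].mean())
        even_rates.append(succ[1::2].mean())
    if len(odd_rates) < 3:
        raise ValueError(
            f"need >= 3 complete participants, found {len(odd_rates)}"
        )
    res = stats.pearsonr(odd_rates, even_rates)
    ci = res.confidence_interval(0.95)
    return float(res.statistic), float(ci.low), float(ci.high)
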