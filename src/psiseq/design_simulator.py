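"""Operating-characteristics simulation of the sequential four-test design.

A *truth model* specifies how the population actually behaves:

* ``fixed`` — every trial succeeds with the same probability p;
* ``beta_sampled`` — one p per simulated experiment, drawn from a
  Beta(a, b) (by default the 829/733 shape pair implied by the seeding
  study), shared by all participants of that experiment;
* ``heterogeneous`` — per-participant chance clip(p + N(0, sd)), the
  large-individual-differences scenario (sd 0.15 puts roughly 10% of
  people above a 70% chance when the mean is 0.51);
* ``sheep_goat`` — a two-point mixture p + delta / p - delta, emulating
  distinct above- and below-chance performer subgroups.

Each replicate simulates participants of 18 erotic trials as binomial
success counts (never materializing individual rows), accumulates the
collapsed (successes, trials) patterns, and runs the full sequential
procedure at each registered analysis point.  Equivalence of this fast
path with row-level generation is asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .sequential_design import (
    DesignConfig,
    LookResult,
    StudyOutcome,
    evaluate_look_from_counts,
)
from .verdicts import Verdict

__all__ = [
    "TruthModel",
    "SimulationPlan",
    "OperatingCharacteristics",
    "draw_participant_chances",
    "simulate_study",
    "operating_characteristics",
]


@dataclass(frozen=True)
class TruthModel:
    """Generative assumption about the population's true guess chance."""

    kind: str = "fixed"  # fixed | beta_sampled | heterogeneous | sheep_goat
    p: float = 0.5
    a: float = 829.0
    b: float = 733.0
    sd: float = 0.15
    mix: tuple[float, float] = (0.1, 0.2)  # (fraction at +delta, delta)

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "beta_sampled", "heterogeneous", "sheep_goat"):
            raise ValueError(f"unknown truth model kind: {self.kind!r}")

    def label(self) -> str:
        if self.kind == "fixed":
            return f"fixed_p={self.p:g}"
        if self.kind == "beta_sampled":
            return f"beta({self.a:g},{self.b:g})"
        if self.kind == "heterogeneous":
            return f"hetero_p={self.p:g}_sd={self.sd:g}"
        return f"sheep_goat_p={self.p:g}_mix={self.mix[0]:g}_delta={self.mix[1]:g}"


def draw_participant_chances(
    truth: TruthModel, n_participants: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-participant success chances for one simulated experiment.

    ``beta_sampled`` draws a single experiment-level p shared by everyone;
    the other kinds vary (or fix) the chance per participant.  Chances are
    clipped to [0, 1] (clipping mass is ~5e-4 at sd 0.15 — negligible but
    deterministic).
    """
    if truth.kind == "fixed":
        return np.full(n_participants, truth.p)
    if truth.kind == "beta_sampled":
        return np.full(n_participants, rng.beta(truth.a, truth.b))
    if truth.kind == "heterogeneous":
        return np.clip(truth.p + rng.normal(0.0, truth.sd, n_participants), 0.0, 1.0)
    frac, delta = truth.mix
    sheep = rng.random(n_participants) < frac
    return np.clip(np.where(sheep, truth.p + delta, truth.p - delta), 0.0, 1.0)


def simulate_study(
    truth: TruthModel,
    cfg: DesignConfig | None = None,
    rng: np.random.Generator | None = None,
    trials_per_participant: int = 18,
) -> StudyOutcome:
    """Simulate one complete study under the sequential design.

    Participants are generated in blocks up to each analysis point; if a
    point is not divisible by the per-participant trial count, the last
    participant of the block contributes a truncated (partial) pattern,
    exactly as a session in progress would at a live analysis point.
    """
    cfg = cfg or DesignConfig()
    rng = rng if rng is not None else np.random.default_rng()
    m = trials_per_participant
    counts: dict[tuple[int, int], int] = {}
    k_total = 0
    n_total = 0
    looks: list[LookResult] = []
    for look, point in enumerate(cfg.analysis_points, start=1):
        need = point - n_total
        n_full, rem = divmod(need, m)
        chances = draw_participant_chances(truth, n_full + (1 if rem else 0), rng)
        ks = rng.binomial(m, chances[:n_full]) if n_full else np.array([], dtype=int)
        for kk in ks:
            key = (int(kk), m)
            counts[key] = counts.get(key, 0) + 1
        k_total += int(ks.sum())
        if rem:
            kp = int(rng.binomial(rem, chances[-1]))
            key = (kp, rem)
            counts[key] = counts.get(key, 0) + 1
            k_total += kp
        n_total = point
        lr = evaluate_look_from_counts(
            counts, k_total, n_total, look, cfg, lazy_mixed=True
        )
        looks.append(lr)
        if lr.conjunction != "continue":
            final = (
                Verdict.SUPPORT_M0
                if lr.conjunction == "stop_support_M0"
                else Verdict.SUPPORT_M1
            )
            return StudyOutcome(
                looks=tuple(looks), final=final, stopped_at_look=look, trials_used=point
            )
    return StudyOutcome(
        looks=tuple(looks),
        final=Verdict.INCONCLUSIVE,
        stopped_at_look=None,
        trials_used=cfg.analysis_points[-1],
    )


@dataclass(frozen=True)
class SimulationPlan:
    """A batch of truth scenarios, replicate counts and the design to test."""

    scenarios: tuple[TruthModel, ...]
    reps: int = 200
    seed: int = 0
    cfg: DesignConfig = field(default_factory=DesignConfig)
    trials_per_participant: int = 18

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        object.__setattr__(self, "scenarios", tuple(self.scenarios))


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Per-scenario outcome frequencies with Monte-Carlo standard errors."""

    table: pd.DataFrame

    def row(self, label: str) -> pd.Series:
        return self.table.set_index("scenario").loc[label]


def operating_characteristics(plan: SimulationPlan) -> OperatingCharacteristics:
    """Estimate P(support M0 / M1 / inconclusive) and stopping behaviour.

    Each (scenario, replicate) pair gets its own independent RNG substream
    spawned from the plan seed, so results are reproducible and individual
    replicates can be re-run in isolation.
    """
    rows = []
    for s_idx, truth in enumerate(plan.scenarios):
        outcomes = {v: 0 for v in Verdict}
        trials_used = np.empty(plan.reps, dtype=np.int64)
        stop_looks: dict[int | None, int] = {}
        for rep in range(plan.reps):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=plan.seed, spawn_key=(s_idx, rep))
            )
            out = simulate_study(truth, plan.cfg, rng, plan.trials_per_participant)
            outcomes[out.final] += 1
            trials_used[rep] = out.trials_used
            stop_looks[out.stopped_at_look] = stop_looks.get(out.stopped_at_look, 0) + 1
        r = plan.reps
        probs = {v: c / r for v, c in outcomes.items()}
        rows.append(
            {
                "scenario": truth.label(),
                "reps": r,
                "p_support_M0": probs[Verdict.SUPPORT_M0],
                "p_support_M1": probs[Verdict.SUPPORT_M1],
                "p_inconclusive": probs[Verdict.INCONCLUSIVE],
                "se_support_M0": _binom_se(probs[Verdict.SUPPORT_M0], r),
                "se_support_M1": _binom_se(probs[Verdict.SUPPORT_M1], r),
                "se_inconclusive": _binom_se(probs[Verdict.INCONCLUSIVE], r),
                "mean_trials_at_stop": float(trials_used.mean()),
                "stop_look_counts": {
                    (k if k is not None else "none"): v
                    for k, v in sorted(
                        stop_looks.items(), key=lambda kv: (kv[0] is None, kv[0] or 0)
                    )
                },
            }
        )
    return OperatingCharacteristics(table=pd.DataFrame(rows))


def _binom_se(p: float, n: int) -> float:
    return float(np.sqrt(p * (1.0 - p) / n))
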