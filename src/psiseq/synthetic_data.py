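"""Synthetic trial-stream generator emulating a multi-lab guessing study.

Every session is 36 forced-choice trials, 18 of which are "erotic" (the
only ones entering hypothesis tests); erotic positions within the session
are a without-replacement draw, mirroring random selection from a 36-image
reward pool.  The participant guesses a side (with a slight empirical
right-side bias), and success on an erotic trial is Bernoulli in the
participant's true chance p_i; the target side is then derived from the
guess and the success flag, which is equivalent to the protocol's
"target drawn after the guess" under any p_i and keeps the truth model
explicit.  Non-erotic successes are drawn at chance — the hypotheses
exclude them.

Operational noise matches observed study rates: ~4.17% of participants
drop out before their first trial, ~1.18% of started sessions terminate
early at a uniformly random trial.  Records receive a global
``deposit_order`` and opaque timestamp hashes, and can be written out in
200-row batches like a born-open deposition stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design_simulator import TruthModel, draw_participant_chances
from .trial_data import CANONICAL_COLUMNS, Provenance, TrialTable

__all__ = ["StudyGenConfig", "generate_session", "generate_study"]


@dataclass(frozen=True)
class StudyGenConfig:
    """Generator parameters; defaults reproduce the observed stream structure."""

    n_participants: int = 200
    n_labs: int = 10
    experimenters_per_lab: int = 3
    trials_per_session: int = 36
    erotic_per_session: int = 18
    truth: TruthModel = field(default_factory=lambda: TruthModel(kind="fixed", p=0.5))
    left_choice_rate: float = 0.4908
    pre_trial_dropout_rate: float = 0.0417
    mid_session_termination_rate: float = 0.0118
    batch_size: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.erotic_per_session > self.trials_per_session:
            raise ValueError("erotic_per_session cannot exceed trials_per_session")
        for name in (
            "left_choice_rate",
            "pre_trial_dropout_rate",
            "mid_session_termination_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def generate_session(
    p_i: float,
    cfg: StudyGenConfig,
    rng: np.random.Generator,
    n_trials: int | None = None,
) -> pd.DataFrame:
    """One session's trials (without identifiers), possibly truncated.

    ``n_trials`` below the session length models an early termination: the
    trial-type sequence is fixed for the whole planned session, then cut.
    """
    if not 0.0 <= p_i <= 1.0:
        raise ValueError("participant chance must lie in [0, 1]")
    m = cfg.trials_per_session
    n_trials = m if n_trials is None else n_trials
    erotic_pos = rng.choice(m, size=cfg.erotic_per_session, replace=False)
    is_erotic = np.zeros(m, dtype=bool)
    is_erotic[erotic_pos] = True
    guessed_left = rng.random(m) < cfg.left_choice_rate
    p_succ = np.where(is_erotic, p_i, 0.5)
    success = rng.random(m) < p_succ
    target_left = np.where(success, guessed_left, ~guessed_left)
    df = pd.DataFrame(
        {
            "trial_index": np.arange(1, m + 1),
            "trial_type": np.where(is_erotic, "erotic", "nonerotic"),
            "guessed_side": np.where(guessed_left, "left", "right"),
            "target_side": np.where(target_left, "left", "right"),
            "success": success,
        }
    )
    return df.iloc[:n_trials].reset_index(drop=True)


def _token(rng: np.random.Generator) -> str:
    return "".join(f"{b:02x}" for b in rng.integers(0, 256, size=8))


def generate_study(cfg: StudyGenConfig) -> TrialTable:
    """Generate a full deposited stream for ``cfg.n_participants`` recruits.

    Dropouts contribute no rows.  Surviving sessions are terminated early
    with the configured probability, at a uniformly random trial before the
    last.  Sessions are deposited one after another in recruitment order;
    ``deposit_order`` is the global row index of that stream.
    """
    rng = np.random.default_rng(cfg.seed)
    chances = draw_participant_chances(cfg.truth, cfg.n_participants, rng)
    frames: list[pd.DataFrame] = []
    next_order = 0
    for i in range(cfg.n_participants):
        lab = int(rng.integers(cfg.n_labs))
        exp = int(rng.integers(cfg.experimenters_per_lab))
        if rng.random() < cfg.pre_trial_dropout_rate:
            continue
        n_trials = None
        if rng.random() < cfg.mid_session_termination_rate:
            n_trials = int(rng.integers(1, cfg.trials_per_session))
        df = generate_session(chances[i], cfg, rng, n_trials)
        df["session_id"] = f"s{i:05d}"
        df["participant_id"] = f"p{i:05d}"
        df["lab_id"] = f"lab{lab:02d}"
        df["experimenter_id"] = f"lab{lab:02d}-e{exp}"
        df["deposit_order"] = np.arange(next_order, next_order + len(df))
        df["timestamp_hash"] = [_token(rng) for _ in range(len(df))]
        df["experimenter_asgs"] = int(rng.integers(0, 37))
        df["sitepi_asgs"] = int(rng.integers(0, 37))
        df["esp_belief"] = int(rng.integers(1, 6))
        df["sensation_seeking"] = int(rng.integers(1, 6))
        next_order += len(df)
        frames.append(df)
    if frames:
        merged = pd.concat(frames, ignore_index=True)[list(CANONICAL_COLUMNS)]
    else:
        merged = pd.DataFrame(columns=list(CANONICAL_COLUMNS))
    prov = Provenance(source=f"synthetic(seed={cfg.seed})", n_rows=len(merged))
    return TrialTable(df=merged, provenance=prov)
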