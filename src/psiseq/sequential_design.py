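"""The four-test conjunction design and its sequential stopping rule.

At each preregistered analysis point (a cumulative count of erotic trials)
four tests are run on the confirmatory set:

1. the random-intercept logistic Wald CI at the Bonferroni-widened level
   for that look, with the SESOI/null bound decision rule;
2.–4. Bayes factors BF01 of the pooled counts under the uniform, BUJ and
   replication priors, each against the 25 / (1/25) thresholds.

Data collection stops at the first look where all four verdicts agree and
are decisive; reaching the final look without such agreement yields an
inconclusive study.  Between looks the Bayes factors (cheap closed forms)
can be tracked per trial as a monitoring trajectory; the mixed model is
only fit at looks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import bayes_inference as bi
from . import frequentist_tests as ft
from . import trial_data as td
from .priors import TruncatedBetaPrior, default_priors
from .verdicts import Verdict

__all__ = [
    "DesignConfig",
    "LookResult",
    "StudyOutcome",
    "evaluate_look",
    "evaluate_look_from_counts",
    "run_study",
    "bf_trajectory",
    "INTERIM_WARNING",
]

#: Banner carried by every interim (between-looks) monitoring report.
INTERIM_WARNING = (
    "Result not yet final! Data presented here represent the current trend "
    "calculated from the data. The results should not be over-interpreted! "
    "Random variations may cause the data to cross the decision thresholds. "
    "Statistical decisions will only be drawn at the pre-specified stopping "
    "points. The next stopping point will be at reaching {next_point} trials."
)

DEFAULT_ANALYSIS_POINTS = (37836, 62388, 86958, 111528, 136080)


@dataclass(frozen=True)
class DesignConfig:
    """Registered design parameters: looks, thresholds, bounds and priors."""

    analysis_points: tuple[int, ...] = DEFAULT_ANALYSIS_POINTS
    bf_upper: float = 25.0
    bf_lower: float = 1.0 / 25.0
    sesoi: float = 0.51
    null_bound: float = 0.50
    base_alpha: float = 0.005
    rope_hi: float = 0.506
    hdi_level: float = 0.90
    priors: tuple[TruncatedBetaPrior, ...] = field(default_factory=default_priors)

    def __post_init__(self) -> None:
        pts = tuple(int(p) for p in self.analysis_points)
        if any(b <= a for a, b in zip(pts, pts[1:])):
            raise ValueError("analysis points must be strictly increasing")
        object.__setattr__(self, "analysis_points", pts)
        if abs(self.bf_lower * self.bf_upper - 1.0) > 1e-9:
            raise ValueError("bf_lower must equal 1 / bf_upper")

    @property
    def n_looks(self) -> int:
        return len(self.analysis_points)

    def ci_level(self, look: int) -> float:
        return ft.ci_level_for_look(look, self.base_alpha)


@dataclass(frozen=True)
class LookResult:
    """All four verdicts at one analysis point plus the conjunction decision."""

    look: int
    n_trials: int
    k: int
    ci: ft.ProbabilityCI | None
    ci_verdict: Verdict | None
    bf01_by_prior: dict[str, float]
    bf_verdicts: dict[str, Verdict]
    conjunction: str  # stop_support_M0 | stop_support_M1 | continue
    mixed_fit: ft.MixedModelFit | None = None

    def to_record(self) -> dict:
        """JSON-serializable summary of this look."""
        return {
            "look": self.look,
            "n_trials": self.n_trials,
            "k": self.k,
            "ci_level": None if self.ci is None else self.ci.level,
            "ci_lo": None if self.ci is None else self.ci.lo,
            "ci_hi": None if self.ci is None else self.ci.hi,
            "ci_verdict": None if self.ci_verdict is None else str(self.ci_verdict),
            "bf01": dict(self.bf01_by_prior),
            "bf_verdicts": {k: str(v) for k, v in self.bf_verdicts.items()},
            "conjunction": self.conjunction,
        }


@dataclass(frozen=True)
class StudyOutcome:
    """Whole-study result of applying the sequential rule to a stream."""

    looks: tuple[LookResult, ...]
    final: Verdict
    stopped_at_look: int | None
    trials_used: int

    def to_record(self) -> dict:
        return {
            "final": str(self.final),
            "stopped_at_look": self.stopped_at_look,
            "trials_used": self.trials_used,
            "looks": [lr.to_record() for lr in self.looks],
        }


def _conjunction(verdicts: Sequence[Verdict]) -> str:
    first = verdicts[0]
    if first.decisive and all(v == first for v in verdicts[1:]):
        return f"stop_{first.value}"
    return "continue"


def evaluate_look_from_counts(
    patterns: Mapping[tuple[int, int], int],
    k: int,
    n: int,
    look: int,
    cfg: DesignConfig,
    lazy_mixed: bool = False,
) -> LookResult:
    """Evaluate one look from sufficient statistics.

    ``lazy_mixed`` skips the mixed-model fit when the three BF verdicts are
    not already unanimous and decisive — the conjunction then continues
    regardless of the CI verdict, so the decision is unchanged.  Used by
    the design simulator's fast path.
    """
    bf_res = bi.bayes_proportion_tests(k, n, cfg.priors, cfg.bf_upper, cfg.bf_lower)
    bf_verdicts = list(bf_res.verdicts.values())
    bf_unanimous = bf_verdicts[0].decisive and all(
        v == bf_verdicts[0] for v in bf_verdicts
    )
    if lazy_mixed and not bf_unanimous:
        return LookResult(
            look=look,
            n_trials=n,
            k=k,
            ci=None,
            ci_verdict=None,
            bf01_by_prior=bf_res.bf01_by_prior,
            bf_verdicts=bf_res.verdicts,
            conjunction="continue",
        )
    fit = ft.fit_patterns(patterns)
    ci = ft.probability_ci(fit, cfg.ci_level(look))
    cv = ft.ci_verdict(ci, cfg.sesoi, cfg.null_bound)
    conj = _conjunction([cv, *bf_verdicts])
    return LookResult(
        look=look,
        n_trials=n,
        k=k,
        ci=ci,
        ci_verdict=cv,
        bf01_by_prior=bf_res.bf01_by_prior,
        bf_verdicts=bf_res.verdicts,
        conjunction=conj,
        mixed_fit=fit,
    )


def evaluate_look(table: td.TrialTable, look: int, cfg: DesignConfig) -> LookResult:
    """Evaluate one look on a confirmatory table truncated to that look's point."""
    expected = cfg.analysis_points[look - 1]
    if len(table) < expected:
        raise td.AnalysisPointNotReached(
            f"look {look} requires {expected} erotic trials, table has {len(table)}"
        )
    if len(table) > expected:
        table = td.TrialTable(df=table.df.iloc[:expected], provenance=table.provenance)
    k, n = td.pooled_success_counts(table)
    patterns = ft.collapse_patterns(table)
    return evaluate_look_from_counts(patterns, k, n, look, cfg)


def run_study(
    stream: td.TrialTable,
    cfg: DesignConfig | None = None,
    inclusion: td.InclusionConfig | None = None,
) -> StudyOutcome:
    """Apply the sequential four-test procedure to a raw deposited stream.

    The stream is confirmatory-filtered once, then truncated to each
    analysis point in turn; the study stops at the first decisive
    conjunction.  A stream shorter than the next required analysis point
    raises :class:`~psiseq.trial_data.AnalysisPointNotReached`.
    """
    cfg = cfg or DesignConfig()
    inclusion = inclusion or td.InclusionConfig()
    confirmatory = td.filter_confirmatory(stream, inclusion)
    looks: list[LookResult] = []
    for look, point in enumerate(cfg.analysis_points, start=1):
        if len(confirmatory) < point:
            raise td.AnalysisPointNotReached(
                f"analysis point not reached: look {look} needs {point} erotic "
                f"trials, stream provides {len(confirmatory)}"
            )
        sub = td.TrialTable(
            df=confirmatory.df.iloc[:point], provenance=confirmatory.provenance
        )
        lr = evaluate_look(sub, look, cfg)
        looks.append(lr)
        if lr.conjunction != "continue":
            final = (
                Verdict.SUPPORT_M0
                if lr.conjunction == "stop_support_M0"
                else Verdict.SUPPORT_M1
            )
            return StudyOutcome(
                looks=tuple(looks),
                final=final,
                stopped_at_look=look,
                trials_used=point,
            )
    return StudyOutcome(
        looks=tuple(looks),
        final=Verdict.INCONCLUSIVE,
        stopped_at_look=None,
        trials_used=cfg.analysis_points[-1],
    )


def bf_trajectory(
    table: td.TrialTable, cfg: DesignConfig | None = None, step: int = 1
) -> list[dict]:
    """Cumulative per-prior BF01 values every ``step`` erotic trials.

    This is the monitoring curve shown between looks in a live report: the
    prefix counts (k, n) after each deposited trial, pushed through the
    closed-form Bayes factor for each registered prior.
    """
    cfg = cfg or DesignConfig()
    if step < 1:
        raise ValueError("step must be >= 1")
    succ = table.df["success"].to_numpy()
    out: list[dict] = []
    cum = succ.cumsum()
    for n in range(step, len(succ) + 1, step):
        k = int(cum[n - 1])
        row: dict = {"n": n, "k": k}
        for p in cfg.priors:
            row[f"bf01_{p.label}"] = bi.bf01(k, n, p)
        out.append(row)
    return out
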