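"""Trial-level data model, CSV readers/writers and inclusion rules.

A study's raw stream is one row per guessing trial, deposited append-only
in small batches ("born-open" style).  The canonical schema is defined
here; arbitrary source headers are mapped onto it with a ``column_map``.
Chronology is carried by ``deposit_order`` (timestamps in the source are
hashed), with ties broken by (session_id, trial_index).

The confirmatory analysis set is derived by:

1. dropping all rows generated by system-test experimenter accounts;
2. keeping only erotic trials (the hypotheses refer to nothing else);
3. optionally truncating strictly after the Nth retained erotic trial —
   the preregistered analysis point — so sessions still in progress
   contribute partial data, exactly as happens in a live stream.

Completed erotic trials of prematurely terminated sessions are retained:
excluding them would let premature-stopping strategies bias the pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "REQUIRED_COLUMNS",
    "Provenance",
    "TrialTable",
    "InclusionConfig",
    "read_trials",
    "write_born_open_batches",
    "filter_confirmatory",
    "pooled_success_counts",
    "participant_success_rates",
    "AnalysisPointNotReached",
    "SchemaError",
]

TRIAL_TYPES = ("erotic", "nonerotic")
SIDES = ("left", "right")

REQUIRED_COLUMNS = (
    "session_id",
    "participant_id",
    "lab_id",
    "experimenter_id",
    "trial_index",
    "trial_type",
    "guessed_side",
    "target_side",
)

OPTIONAL_COLUMNS = (
    "success",
    "deposit_order",
    "timestamp_hash",
    "experimenter_asgs",
    "sitepi_asgs",
    "esp_belief",
    "sensation_seeking",
)

CANONICAL_COLUMNS = REQUIRED_COLUMNS + OPTIONAL_COLUMNS

_INT_OPTIONAL = ("experimenter_asgs", "sitepi_asgs", "esp_belief", "sensation_seeking")


class SchemaError(ValueError):
    """A required column is missing or a configuration is inconsistent."""


class AnalysisPointNotReached(ValueError):
    """The stream holds fewer retained erotic trials than the analysis point."""


@dataclass(frozen=True)
class Provenance:
    """Where a table came from and how many rows were dropped on the way."""

    source: str
    n_rows: int
    n_excluded: int = 0
    excluded_rows: tuple[int, ...] = ()
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class TrialTable:
    """Ordered sequence of trial records with read/filter provenance.

    ``df`` always carries the canonical columns, sorted by deposit_order
    with (session_id, trial_index) as tie-break.
    """

    df: pd.DataFrame
    provenance: Provenance = field(
        default_factory=lambda: Provenance(source="memory", n_rows=0)
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "df", _canonicalize(self.df))

    def __len__(self) -> int:
        return len(self.df)

    def equals(self, other: "TrialTable") -> bool:
        """Equality on canonical fields (provenance excluded)."""
        a = self.df.reset_index(drop=True)
        b = other.df.reset_index(drop=True)
        return a.equals(b)


@dataclass(frozen=True)
class InclusionConfig:
    """Preregistered inclusion rules for the confirmatory set."""

    test_experimenter_ids: frozenset[str] = frozenset()
    analysis_point: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "test_experimenter_ids", frozenset(self.test_experimenter_ids)
        )
        if self.analysis_point is not None and self.analysis_point < 1:
            raise ValueError("analysis_point must be a positive integer")


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            if col == "success":
                df[col] = df["guessed_side"] == df["target_side"]
            elif col == "deposit_order":
                df[col] = np.arange(len(df), dtype=np.int64)
            elif col == "timestamp_hash":
                df[col] = ""
            else:
                df[col] = pd.NA
    df["trial_index"] = df["trial_index"].astype(np.int64)
    df["deposit_order"] = df["deposit_order"].astype(np.int64)
    df["success"] = df["success"].astype(bool)
    for col in _INT_OPTIONAL:
        df[col] = df[col].astype("Int64")
    df = df[list(CANONICAL_COLUMNS)]
    df = df.sort_values(
        ["deposit_order", "session_id", "trial_index"], kind="mergesort"
    ).reset_index(drop=True)
    return df


_TRUE_TOKENS = {"true", "1", "t", "yes"}
_FALSE_TOKENS = {"false", "0", "f", "no"}


def read_trials(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> TrialTable:
    """Read a delimited trial file into a :class:`TrialTable`.

    ``column_map`` maps canonical field names to the source file's headers;
    omitted fields are assumed to use canonical names.  Rows that fail
    validation (unknown side/type tokens, non-integer trial index,
    success flag inconsistent with the sides) are excluded and counted in
    the provenance with their 1-based data row numbers — never repaired.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    column_map = dict(column_map or {})

    rename: dict[str, str] = {}
    for canonical in CANONICAL_COLUMNS:
        source = column_map.get(canonical, canonical)
        if source in raw.columns:
            rename[source] = canonical
    for canonical in REQUIRED_COLUMNS:
        if canonical not in rename.values():
            raise SchemaError(
                f"required column {column_map.get(canonical, canonical)!r} "
                f"(canonical {canonical!r}) not found in {path.name}"
            )
    df = raw.rename(columns=rename)
    df = df[[c for c in CANONICAL_COLUMNS if c in df.columns]]

    bad = pd.Series(False, index=df.index)
    reasons: dict[int, str] = {}

    def _flag(mask: pd.Series, reason: str) -> None:
        for idx in df.index[mask & ~bad]:
            reasons[int(idx)] = reason
        bad.loc[mask] = True

    _flag(~df["trial_type"].str.lower().isin(TRIAL_TYPES), "invalid trial_type")
    for col in ("guessed_side", "target_side"):
        _flag(~df[col].str.lower().isin(SIDES), f"invalid {col}")
    _flag(~df["trial_index"].str.fullmatch(r"\d+").fillna(False), "invalid trial_index")
    if "deposit_order" in df.columns:
        _flag(
            ~df["deposit_order"].str.fullmatch(r"\d+").fillna(False),
            "invalid deposit_order",
        )
    if "success" in df.columns:
        tokens = df["success"].str.lower()
        _flag(~tokens.isin(_TRUE_TOKENS | _FALSE_TOKENS), "invalid success flag")
        parsed = tokens.isin(_TRUE_TOKENS)
        consistent = parsed == (
            df["guessed_side"].str.lower() == df["target_side"].str.lower()
        )
        _flag(~consistent & ~bad, "success inconsistent with sides")

    excluded_rows = tuple(int(i) + 1 for i in sorted(reasons))  # 1-based data rows
    good = df.loc[~bad].copy()
    for col in ("trial_type", "guessed_side", "target_side"):
        good[col] = good[col].str.lower()
    good["trial_index"] = good["trial_index"].astype(np.int64)
    if "deposit_order" in good.columns:
        good["deposit_order"] = good["deposit_order"].astype(np.int64)
    if "success" in good.columns:
        good["success"] = good["success"].str.lower().isin(_TRUE_TOKENS)
    for col in _INT_OPTIONAL:
        if col in good.columns:
            good[col] = pd.to_numeric(good[col], errors="coerce").astype("Int64")

    prov = Provenance(
        source=str(path),
        n_rows=len(raw),
        n_excluded=len(excluded_rows),
        excluded_rows=excluded_rows,
        notes=tuple(f"row {i + 1}: {r}" for i, r in sorted(reasons.items())),
    )
    return TrialTable(df=good, provenance=prov)


def write_born_open_batches(
    table: TrialTable, batch_size: int, sink: str | Path
) -> list[Path]:
    """Write the table as consecutive fixed-size CSV batches in deposit order.

    Mirrors batched live deposition: files are append-only slices whose
    concatenation reproduces the table; the last batch may be short.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    sink = Path(sink)
    sink.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    df = table.df
    n_batches = max(1, -(-len(df) // batch_size)) if len(df) else 0
    for i in range(n_batches):
        chunk = df.iloc[i * batch_size : (i + 1) * batch_size]
        p = sink / f"batch_{i:05d}.csv"
        chunk.to_csv(p, index=False)
        paths.append(p)
    return paths


def read_born_open_batches(paths: Iterable[str | Path]) -> TrialTable:
    """Concatenate batch files (in name order) back into one table."""
    frames = [pd.read_csv(p, dtype=str, keep_default_na=False) for p in sorted(map(Path, paths))]
    if not frames:
        return TrialTable(df=pd.DataFrame(columns=list(CANONICAL_COLUMNS)))
    import tempfile

    merged = pd.concat(frames, ignore_index=True)
    with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as fh:
        merged.to_csv(fh, index=False)
        tmp = fh.name
    try:
        return read_trials(tmp)
    finally:
        Path(tmp).unlink(missing_ok=True)


def filter_confirmatory(table: TrialTable, cfg: InclusionConfig) -> TrialTable:
    """Apply the preregistered inclusion rules; see module docstring.

    Raises :class:`AnalysisPointNotReached` if fewer retained erotic trials
    exist than the configured analysis point.
    """
    df = table.df
    keep = df["trial_type"] == "erotic"
    if cfg.test_experimenter_ids:
        keep &= ~df["experimenter_id"].isin(cfg.test_experimenter_ids)
    out = df.loc[keep]
    dropped = len(df) - len(out)
    if cfg.analysis_point is not None:
        if len(out) < cfg.analysis_point:
            raise AnalysisPointNotReached(
                f"analysis point not reached: {len(out)} retained erotic trials "
                f"< {cfg.analysis_point}"
            )
        dropped += len(out) - cfg.analysis_point
        out = out.iloc[: cfg.analysis_point]
    prov = replace(
        table.provenance,
        n_rows=len(out),
        n_excluded=table.provenance.n_excluded + dropped,
        notes=table.provenance.notes + (f"confirmatory filter dropped {dropped} rows",),
    )
    return TrialTable(df=out.reset_index(drop=True), provenance=prov)


def pooled_success_counts(table: TrialTable) -> tuple[int, int]:
    """Pooled (successes, trials) over the whole table.

    Pooling across participants is what makes the Bayesian proportion tests
    immune to premature-stopping strategies: every completed trial counts,
    regardless of who contributed it or whether the session finished.
    """
    n = len(table.df)
    k = int(table.df["success"].sum()) if n else 0
    return k, n


def participant_success_rates(
    table: TrialTable, required_trials: int = 18
) -> dict[str, float]:
    """Per-participant success rate, restricted to complete participants.

    Only participants with exactly ``required_trials`` retained erotic
    trials are included (partial sessions would otherwise distort the rate
    distribution).
    """
    if required_trials < 1:
        raise ValueError("required_trials must be >= 1")
    g = table.df.groupby("participant_id", sort=True)["success"].agg(["sum", "count"])
    g = g[g["count"] == required_trials]
    return {str(pid): float(s) / required_trials for pid, s in g["sum"].items()}
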